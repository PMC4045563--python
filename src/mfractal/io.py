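"""Plain-text serialization: CSV for tabular data, JSON for reports/models.

Formats
-------
signal        single-column CSV, header ``value``
K_q(d) table  tidy CSV, columns ``q, d, K``
spectrum      CSV ``q, H, slope, r_squared`` (or JSON)
features      CSV ``image_id, H1..Hp[, label]`` — one row per image
report        JSON with metrics plus the per-fold table
model         JSON with support vectors, alphas, bias, standardization
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mfractal.classify import (
    ClassifierConfig,
    EvaluationReport,
    LabeledDataset,
    TrainedModel,
)
from mfractal.errors import InvalidInputError
from mfractal.msa import HurstSpectrum, Signal1D, StructureFunctionTable


# -- signals ---------------------------------------------------------------

def write_signal(signal: Signal1D, path: str | Path) -> None:
    # %.17g keeps doubles exactly round-trippable through text
    pd.DataFrame({"value": signal.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_signal(path: str | Path) -> Signal1D:
    df = pd.read_csv(path, float_precision="round_trip")
    if "value" not in df.columns:
        raise InvalidInputError(f"{path}: expected a 'value' column")
    return Signal1D(df["value"].to_numpy(dtype=np.float64))


# -- structure-function tables --------------------------------------------

def write_table(table: StructureFunctionTable, path: str | Path) -> None:
    qq, dd = np.meshgrid(table.q_values, table.d_values, indexing="ij")
    pd.DataFrame(
        {"q": qq.ravel(), "d": dd.ravel().astype(int), "K": table.K.ravel()}
    ).to_csv(path, index=False)


def read_table(path: str | Path) -> StructureFunctionTable:
    df = pd.read_csv(path, float_precision="round_trip")
    q_values = np.unique(df["q"].to_numpy())
    d_values = np.unique(df["d"].to_numpy())
    K = (
        df.pivot(index="q", columns="d", values="K")
        .loc[q_values, d_values]
        .to_numpy()
    )
    return StructureFunctionTable(q_values=q_values, d_values=d_values, K=K)


# -- Hurst spectra ---------------------------------------------------------

def write_spectrum(spectrum: HurstSpectrum, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(
            json.dumps(
                {
                    "q": spectrum.q_values.tolist(),
                    "H": spectrum.H.tolist(),
                    "slope": spectrum.slope.tolist(),
                    "r_squared": spectrum.r_squared.tolist(),
                },
                indent=2,
            )
        )
    else:
        pd.DataFrame(
            {
                "q": spectrum.q_values,
                "H": spectrum.H,
                "slope": spectrum.slope,
                "r_squared": spectrum.r_squared,
            }
        ).to_csv(path, index=False)


# -- feature tables --------------------------------------------------------

def write_features(
    ids: "list[str]",
    spectra: "list[HurstSpectrum]",
    path: str | Path,
    labels: "list[int] | None" = None,
) -> None:
    """One row per image: image_id, H1..Hp, and a label column when known."""
    if not spectra:
        raise InvalidInputError("no feature rows to write")
    p = spectra[0].H.size
    cols = {"image_id": ids}
    for j in range(p):
        cols[f"H{j + 1}"] = [s.H[j] for s in spectra]
    if labels is not None:
        cols["label"] = labels
    pd.DataFrame(cols).to_csv(path, index=False)


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    p = dataset.features.shape[1]
    cols = {"image_id": list(dataset.ids)}
    for j in range(p):
        cols[f"H{j + 1}"] = dataset.features[:, j]
    cols["label"] = dataset.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def read_dataset(path: str | Path, require_label: bool = True) -> LabeledDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    feat_cols = [c for c in df.columns if c.startswith("H") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    if not feat_cols:
        raise InvalidInputError(f"{path}: no feature columns H1..Hp found")
    if require_label and "label" not in df.columns:
        raise InvalidInputError(f"{path}: missing 'label' column")
    labels = (
        df["label"].to_numpy(dtype=np.int64)
        if "label" in df.columns
        else np.full(len(df), -1, dtype=np.int64)
    )
    ids = (
        df["image_id"].astype(str).tolist()
        if "image_id" in df.columns
        else [str(i) for i in range(len(df))]
    )
    return LabeledDataset(
        features=df[feat_cols].to_numpy(dtype=np.float64),
        labels=labels,
        ids=tuple(ids),
    )


# -- evaluation reports ----------------------------------------------------

def report_to_dict(report: EvaluationReport) -> dict:
    return {
        "metrics": {
            "ccr": report.ccr,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "ccr_std": report.ccr_std,
            "sens_std": report.sens_std,
            "spec_std": report.spec_std,
        },
        "per_fold": [
            {"id": i, "true": t, "predicted": p} for i, t, p in report.per_fold
        ],
    }


def write_report(report: EvaluationReport, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(
            report.per_fold, columns=["id", "true", "predicted"]
        ).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(report_to_dict(report), indent=2))


# -- trained models --------------------------------------------------------

def write_model(model: TrainedModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "support_vectors": model.support_vectors.tolist(),
                "alphas": model.alphas.tolist(),
                "support_labels": model.support_labels.tolist(),
                "bias": model.bias,
                "loc": model.loc.tolist(),
                "scale": model.scale.tolist(),
                "config": {
                    "degree": model.config.degree,
                    "C": model.config.C,
                    "standardize": model.config.standardize,
                },
            },
            indent=2,
        )
    )


def read_model(path: str | Path) -> TrainedModel:
    obj = json.loads(Path(path).read_text())
    cfg = obj["config"]
    return TrainedModel(
        support_vectors=np.asarray(obj["support_vectors"], dtype=np.float64),
        alphas=np.asarray(obj["alphas"], dtype=np.float64),
        support_labels=np.asarray(obj["support_labels"], dtype=np.int64),
        bias=float(obj["bias"]),
        loc=np.asarray(obj["loc"], dtype=np.float64),
        scale=np.asarray(obj["scale"], dtype=np.float64),
        config=ClassifierConfig(
            degree=int(cfg["degree"]),
            C=float(cfg["C"]),
            standardize=bool(cfg["standardize"]),
        ),
    )
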