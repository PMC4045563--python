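"""Polynomial-kernel soft-margin SVM and leave-one-out evaluation.

The classifier is the standard two-class soft-margin SVM with the
inhomogeneous polynomial kernel K(x, y) = (x.y + 1)^degree.  The dual
quadratic program is solved by scikit-learn's SVC; the trained model is
then re-expressed in primal-free form — support vectors x_i, multipliers
alpha_i, labels y_i and bias b — and predictions are computed in-package
as sign(sum_i y_i alpha_i K(x, x_i) + b), with a decision value of
exactly 0 mapped to the negative class.

Features are z-scored with location/scale estimated from the training
data only (polynomial kernels are scale-sensitive); the parameters are
stored in the model so held-out samples are standardized consistently.

Evaluation follows the leave-one-out protocol: each sample is predicted
by a model trained on all the others, and the correct classification
rate (CCR), sensitivity (correct rate among positives) and specificity
(correct rate among negatives) are aggregated over the held-out
predictions.  The reported dispersions are the sample standard
deviations of the per-fold 0/1 correctness indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from mfractal.errors import (
    DegenerateTrainingError,
    InsufficientDataError,
    InvalidInputError,
)

#: label conventions: +1 = positive (diseased), -1 = negative (normal)
POSITIVE, NEGATIVE = 1, -1


@dataclass(frozen=True)
class LabeledDataset:
    """Feature vectors with binary labels in {+1, -1} and per-sample ids."""

    features: np.ndarray
    labels: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64).ravel()
        if X.ndim != 2:
            raise InvalidInputError(f"features must be 2D, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("features contain non-finite values")
        if not set(np.unique(y)) <= {POSITIVE, NEGATIVE}:
            raise InvalidInputError("labels must be +1 or -1")
        ids = tuple(str(i) for i in self.ids)
        if not (X.shape[0] == y.size == len(ids)):
            raise InvalidInputError("features, labels and ids must have equal length")
        X.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM hyperparameters: kernel degree, penalty C, standardization."""

    degree: int = 4
    C: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 1 <= int(self.degree) <= 10:
            raise InvalidInputError(f"degree must be in 1..10, got {self.degree}")
        if not self.C > 0:
            raise InvalidInputError(f"C must be positive, got {self.C}")


@dataclass(frozen=True)
class TrainedModel:
    """A trained SVM in dual (support-vector) form.

    Satisfies the dual constraints sum_i alpha_i y_i = 0 (to numerical
    tolerance) and 0 <= alpha_i <= C.  ``loc``/``scale`` are the
    per-feature standardization parameters from the training data
    (identity transform when standardization is off).
    """

    support_vectors: np.ndarray
    alphas: np.ndarray
    support_labels: np.ndarray
    bias: float
    loc: np.ndarray
    scale: np.ndarray
    config: ClassifierConfig


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold LOOCV predictions and aggregate metrics.

    ``per_fold`` rows are (id, true label, predicted label).  ``ccr`` is
    correct predictions over total samples; sensitivity and specificity
    are the correct rates within the positive and negative class
    respectively.  The ``*_std`` fields are sample standard deviations of
    the corresponding per-fold 0/1 outcomes.
    """

    per_fold: tuple[tuple[str, int, int], ...]
    ccr: float
    sensitivity: float
    specificity: float
    ccr_std: float
    sens_std: float
    spec_std: float


def polynomial_kernel(
    x: np.ndarray, y: np.ndarray, degree: int
) -> "float | np.ndarray":
    """Inhomogeneous polynomial kernel (x.y + 1)^degree.

    Accepts single vectors or 2D arrays of row vectors; with arrays the
    full Gram matrix is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if int(degree) < 1:
        raise InvalidInputError(f"degree must be >= 1, got {degree}")
    if x.shape[-1] != y.shape[-1]:
        raise InvalidInputError(
            f"dimension mismatch: {x.shape[-1]} vs {y.shape[-1]}"
        )
    if x.ndim == 1 and y.ndim == 1:
        return float((np.dot(x, y) + 1.0) ** degree)
    return (np.atleast_2d(x) @ np.atleast_2d(y).T + 1.0) ** degree


def _standardization(X: np.ndarray, on: bool) -> tuple[np.ndarray, np.ndarray]:
    p = X.shape[1]
    if not on:
        return np.zeros(p), np.ones(p)
    loc = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0.0, 1.0, scale)  # constant feature: leave centered
    return loc, scale


def train(
    dataset: LabeledDataset, config: ClassifierConfig = ClassifierConfig()
) -> TrainedModel:
    """Fit the soft-margin polynomial-kernel SVM on a labeled dataset.

    The dual QP is solved by scikit-learn's SVC with kernel
    (x.y + 1)^degree (gamma=1, coef0=1); the solution is stored as
    support vectors, multipliers alpha_i > 0, their labels and the bias.
    """
    y = dataset.labels
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("training data contains a single class")
    loc, scale = _standardization(dataset.features, config.standardize)
    Xs = (dataset.features - loc) / scale
    svc = SVC(
        kernel="poly",
        degree=config.degree,
        gamma=1.0,
        coef0=1.0,
        C=config.C,
    )
    svc.fit(Xs, y)
    # dual_coef_ holds alpha_i * y_i for the support vectors
    dual = svc.dual_coef_.ravel()
    return TrainedModel(
        support_vectors=svc.support_vectors_.copy(),
        alphas=np.abs(dual),
        support_labels=np.sign(dual).astype(np.int64),
        bias=float(svc.intercept_[0]),
        loc=loc,
        scale=scale,
        config=config,
    )


def decision_value(model: TrainedModel, feature: np.ndarray) -> float:
    """Evaluate the kernel expansion sum_i y_i alpha_i K(x, x_i) + b."""
    x = np.asarray(feature, dtype=np.float64).ravel()
    if x.size != model.support_vectors.shape[1]:
        raise InvalidInputError(
            f"feature has dimension {x.size}, model expects "
            f"{model.support_vectors.shape[1]}"
        )
    xs = (x - model.loc) / model.scale
    k = polynomial_kernel(model.support_vectors, xs[None, :], model.config.degree)
    return float(
        np.sum(model.alphas * model.support_labels * np.ravel(k)) + model.bias
    )


def predict(model: TrainedModel, feature: np.ndarray) -> int:
    """Predict the class label of one feature vector.

    Returns +1 when the decision value is strictly positive, else -1
    (a decision value of exactly zero maps to the negative class).
    """
    return POSITIVE if decision_value(model, feature) > 0.0 else NEGATIVE


def _metrics(
    true: np.ndarray, pred: np.ndarray
) -> tuple[float, float, float, float, float, float]:
    correct = (true == pred).astype(np.float64)
    pos = true == POSITIVE
    neg = ~pos

    def _std(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    ccr = float(correct.mean())
    sens = float(correct[pos].mean())
    spec = float(correct[neg].mean())
    return ccr, sens, spec, _std(correct), _std(correct[pos]), _std(correct[neg])


def evaluate_loocv(
    dataset: LabeledDataset, config: ClassifierConfig = ClassifierConfig()
) -> EvaluationReport:
    """Leave-one-out cross-validation with CCR/sensitivity/specificity.

    Each sample is predicted by a model trained on all the others;
    standardization parameters are re-estimated inside every fold from
    the training split only, so no information about the held-out sample
    leaks into the transform.

    Raises
    ------
    InsufficientDataError
        If either class has fewer than 2 samples (some training fold
        would be single-class).
    """
    y = dataset.labels
    n = len(dataset)
    if np.sum(y == POSITIVE) < 2 or np.sum(y == NEGATIVE) < 2:
        raise InsufficientDataError(
            "LOOCV needs at least 2 samples per class"
        )
    preds = np.empty(n, dtype=np.int64)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = LabeledDataset(
            features=dataset.features[mask],
            labels=y[mask],
            ids=tuple(np.array(dataset.ids)[mask]),
        )
        model = train(fold, config)
        preds[i] = predict(model, dataset.features[i])
    ccr, sens, spec, ccr_sd, sens_sd, spec_sd = _metrics(y, preds)
    per_fold = tuple(
        (dataset.ids[i], int(y[i]), int(preds[i])) for i in range(n)
    )
    return EvaluationReport(
        per_fold=per_fold,
        ccr=ccr,
        sensitivity=sens,
        specificity=spec,
        ccr_std=ccr_sd,
        sens_std=sens_sd,
        spec_std=spec_sd,
    )
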