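"""Synthetic signals and textures with known fractal structure.

These generators provide ground truth for every pipeline stage without
any external image data: symmetric random walks (H = 0.5 by
construction), exact fractional Brownian motion with a prescribed Hurst
parameter (circulant-embedding / Davies-Harte synthesis of fractional
Gaussian noise, then a cumulative sum), and two-class 2D fractal
textures whose power-law spectra give the classes distinct Hurst
feature vectors — a stand-in for the normal-versus-diseased texture
contrast in real MRI.  Everything is fully determined by (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mfractal.classify import LabeledDataset, NEGATIVE, POSITIVE
from mfractal.errors import InvalidInputError, SynthesisError
from mfractal.image import GrayscaleImage, extract_features
from mfractal.msa import DEFAULT_D_MAX, DEFAULT_Q_VALUES, Signal1D

#: pilot-calibrated defaults for the two-class texture dataset:
#: smoother (+1, "diseased") vs rougher (-1, "normal") surfaces
DEFAULT_CLASS_ROUGHNESS: tuple[float, float] = (0.7, 0.3)
DEFAULT_TEXTURE_SIZE: int = 128


@dataclass(frozen=True)
class FbmSpec:
    """Specification of one fractional Brownian motion realization.

    ``length`` must be a power of two >= 1024 (keeps the circulant
    embedding well-conditioned and the FFT fast); ``hurst`` in (0, 1).
    """

    length: int
    hurst: float
    seed: int

    def __post_init__(self) -> None:
        T = int(self.length)
        if T < 1024 or (T & (T - 1)) != 0:
            raise InvalidInputError(
                f"length must be a power of two >= 1024, got {self.length}"
            )
        if not 0.0 < self.hurst < 1.0:
            raise InvalidInputError(
                f"hurst must lie in (0, 1), got {self.hurst}"
            )


@dataclass(frozen=True)
class TextureSpec:
    """Specification of one 2D fractal texture.

    ``roughness`` in (0, 1) is the spectral-synthesis exponent: the
    amplitude spectrum decays as f^-(roughness+1), so larger values give
    smoother surfaces and larger apparent Hurst exponents.
    """

    height: int = DEFAULT_TEXTURE_SIZE
    width: int = DEFAULT_TEXTURE_SIZE
    roughness: float = 0.5
    seed: int = 0
    class_label: int = NEGATIVE

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise InvalidInputError("texture dimensions must be >= 32")
        if not 0.0 < self.roughness < 1.0:
            raise InvalidInputError(
                f"roughness must lie in (0, 1), got {self.roughness}"
            )
        if self.class_label not in (POSITIVE, NEGATIVE):
            raise InvalidInputError("class_label must be +1 or -1")


def generate_random_walk(T: int, seed: int) -> Signal1D:
    """Symmetric random walk: cumulative sum of i.i.d. +/-1 steps.

    The canonical H = 0.5 test signal.
    """
    if T < 2:
        raise InvalidInputError(f"T must be >= 2, got {T}")
    rng = np.random.default_rng(seed)
    steps = rng.choice((-1.0, 1.0), size=T)
    return Signal1D(np.cumsum(steps))


def _fgn_davies_harte(T: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    The fGn autocovariance gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2
    is embedded in a circulant matrix of order 2T whose eigenvalues are
    the FFT of its first row; these are nonnegative for H in (0, 1), and
    an FFT of suitably scaled complex Gaussians yields a sample with the
    exact target covariance.
    """
    k = np.arange(T + 1, dtype=np.float64)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2T
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8:
        raise SynthesisError(
            f"circulant embedding not nonnegative definite (min eig {lam.min():.3e})"
        )
    lam = np.clip(lam, 0.0, None)
    M = 2 * T
    z = rng.standard_normal(M) + 1j * rng.standard_normal(M)
    # Hermitian-symmetrized spectral sample; real part of the FFT has the
    # target covariance after 1/sqrt(2M) scaling of interior frequencies
    w = np.empty(M, dtype=np.complex128)
    w[0] = np.sqrt(lam[0] / M) * z[0].real
    w[T] = np.sqrt(lam[T] / M) * z[T].real
    idx = np.arange(1, T)
    w[idx] = np.sqrt(lam[idx] / (2 * M)) * z[idx]
    w[M - idx] = np.conj(w[idx])
    return np.fft.fft(w).real[:T]


def generate_fbm(spec: FbmSpec) -> Signal1D:
    """Fractional Brownian motion with exact covariance.

    Synthesizes fractional Gaussian noise by circulant embedding and
    accumulates it; the increments of the result have exactly the fGn
    covariance for the requested Hurst parameter.
    """
    rng = np.random.default_rng(spec.seed)
    fgn = _fgn_davies_harte(spec.length, spec.hurst, rng)
    return Signal1D(np.cumsum(fgn))


def generate_texture(spec: TextureSpec) -> GrayscaleImage:
    """2D fractal texture by spectral synthesis, rescaled to [0, 1].

    White Gaussian noise is shaped in the Fourier domain with a radial
    power-law amplitude filter f^-(roughness+1) (the 2D analogue of a
    self-affine surface with Hurst exponent ~= roughness), inverted, and
    min-max rescaled to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill the DC term
    amp = f ** -(spec.roughness + 1.0)
    noise = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    surface = np.fft.ifft2(amp * noise).real
    lo, hi = surface.min(), surface.max()
    if hi == lo:  # constant surface cannot occur with Gaussian noise, but be safe
        pixels = np.zeros((h, w))
    else:
        pixels = (surface - lo) / (hi - lo)
    return GrayscaleImage(pixels=pixels, source_depth=8)


def generate_dataset(
    n_per_class: int = 20,
    class_roughness: tuple[float, float] = DEFAULT_CLASS_ROUGHNESS,
    seed: int = 0,
    size: int = DEFAULT_TEXTURE_SIZE,
    q_values: "tuple[float, ...] | np.ndarray" = DEFAULT_Q_VALUES,
    d_max: int = DEFAULT_D_MAX,
    return_images: bool = False,
) -> "LabeledDataset | tuple[LabeledDataset, list[GrayscaleImage]]":
    """Two-class texture dataset with extracted Hurst feature vectors.

    Class +1 uses ``class_roughness[0]`` and class -1 uses
    ``class_roughness[1]``; per-image seeds are spawned deterministically
    from ``seed``, so the same seed reproduces the dataset exactly.

    Returns the labeled feature dataset, and the generated images as
    well when ``return_images`` is set.
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    rough_pos, rough_neg = class_roughness
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    feats, labels, ids, images = [], [], [], []
    for label, rough, tag in (
        (POSITIVE, rough_pos, "pos"),
        (NEGATIVE, rough_neg, "neg"),
    ):
        for i in range(n_per_class):
            child = int(child_seeds[(0 if label == POSITIVE else n_per_class) + i])
            img = generate_texture(
                TextureSpec(
                    height=size,
                    width=size,
                    roughness=rough,
                    seed=child % 2**31,
                    class_label=label,
                )
            )
            spectrum = extract_features(img, q_values=q_values, d_max=d_max)
            feats.append(spectrum.H)
            labels.append(label)
            ids.append(f"{tag}_{i:03d}")
            if return_images:
                images.append(img)
    dataset = LabeledDataset(
        features=np.asarray(feats), labels=np.asarray(labels), ids=tuple(ids)
    )
    return (dataset, images) if return_images else dataset
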