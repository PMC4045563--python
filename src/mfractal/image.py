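"""Grayscale image loading and image-to-signal conversion.

A 2D intensity array is turned into a 1D signal by row concatenation
(rows top to bottom, columns left to right within each row), after
normalizing integer intensities to double precision in [0, 1].  The
generalized Hurst spectrum of that signal is the image's texture feature
vector.  No masking, cropping or segmentation is applied: the method is
deliberately global.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from mfractal.errors import (
    InsufficientLengthError,
    InvalidImageError,
    InvalidInputError,
)
from mfractal.msa import (
    DEFAULT_D_MAX,
    DEFAULT_Q_VALUES,
    HurstSpectrum,
    Signal1D,
    estimate_hurst,
    structure_function_table,
)

# ITU-R BT.601 luminance weights, the standard grayscale collapse.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayscaleImage:
    """A 2D grayscale intensity array plus its source bit depth.

    ``pixels`` may hold raw integer intensities (0..2^depth - 1) straight
    from a file, or normalized doubles in [0, 1] after :func:`to_double`.
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise InvalidImageError(
                f"expected a nonempty 2D array, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidImageError("pixel values must be finite and nonnegative")
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def load_image(path: str | Path) -> GrayscaleImage:
    """Load a PNG/TIFF/JPEG file as a grayscale intensity array.

    Multi-channel images are collapsed to luminance with the standard
    BT.601 weights; 16-bit inputs keep their full range.  Values are NOT
    normalized here — see :func:`to_double`.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode in ("I;16", "I;16B", "I;16L", "I"):
                arr = np.asarray(im, dtype=np.float64)
                depth = 16
            elif mode in ("L", "P", "1"):
                arr = np.asarray(im.convert("L"), dtype=np.float64)
                depth = 8
            else:
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                arr = rgb @ _LUMA
                depth = 8
    except (UnidentifiedImageError, OSError) as exc:
        raise InvalidImageError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidImageError(f"{path}: decoded to empty or non-2D array")
    return GrayscaleImage(pixels=arr, source_depth=depth)


def to_double(image: GrayscaleImage) -> GrayscaleImage:
    """Normalize intensities to double precision in [0, 1].

    Integer intensities are divided by the full-scale value
    ``2**source_depth - 1`` (255 for 8-bit).  Idempotent: input already
    within [0, 1] is returned unchanged.
    """
    px = image.pixels
    if px.max(initial=0.0) <= 1.0:
        return image
    scale = float(2**image.source_depth - 1)
    if px.max() > scale:
        raise InvalidInputError(
            f"pixel values exceed stated bit depth {image.source_depth}"
        )
    return GrayscaleImage(pixels=px / scale, source_depth=image.source_depth)


def concatenate_rows(
    image: GrayscaleImage, d_max: int = DEFAULT_D_MAX
) -> Signal1D:
    """Flatten an image to a 1D signal by row concatenation.

    Element ``r*W + c`` of the signal is the pixel at row ``r``, column
    ``c`` (row-major, top to bottom).  A 256x256 image yields T = 65536.

    Raises
    ------
    InsufficientLengthError
        If H*W < d_max + 2, too short for the configured analysis.
    """
    h, w = image.shape
    if h * w < d_max + 2:
        raise InsufficientLengthError(
            f"image of {h}x{w} = {h * w} pixels too short for d_max={d_max}"
        )
    return Signal1D(image.pixels.ravel(order="C"))


def extract_features(
    image: GrayscaleImage,
    q_values: "tuple[float, ...] | np.ndarray" = DEFAULT_Q_VALUES,
    d_max: int = DEFAULT_D_MAX,
) -> HurstSpectrum:
    """Compute the Hurst-spectrum feature vector of a grayscale image.

    Pipeline: normalize to [0,1], row-concatenate, tabulate K_q(d) for
    d = 1..d_max, regress log K_q(d) on log d.  Deterministic, and exactly
    invariant under global intensity rescaling of the image.
    """
    sig = concatenate_rows(to_double(image), d_max=d_max)
    return estimate_hurst(structure_function_table(sig, q_values, d_max))
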