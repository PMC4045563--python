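"""Exception hierarchy for mfractal.

All package errors derive from :class:`MfractalError` so callers can catch
one base class; subclasses name the contract that was violated.
"""


class MfractalError(Exception):
    """Base class for all mfractal errors."""


class DegenerateSignalError(MfractalError):
    """Signal cannot support the analysis (all-zero, or a zero structure
    function makes the log-log regression undefined)."""


class InvalidLagError(MfractalError):
    """Requested lag d is out of range for the signal length."""


class InsufficientLagsError(MfractalError):
    """Fewer than two distinct lags: the log-log regression is undetermined."""


class InsufficientLengthError(MfractalError):
    """Signal (or flattened image) too short for the configured d_max."""


class InvalidImageError(MfractalError):
    """Image file exists but does not decode to a usable 2D intensity array."""


class InvalidInputError(MfractalError):
    """Malformed numeric input: dimension mismatch, non-finite values."""


class DegenerateTrainingError(MfractalError):
    """Training set does not contain both classes."""


class InsufficientDataError(MfractalError):
    """Too few samples per class for the requested evaluation protocol."""


class SynthesisError(MfractalError):
    """Exact fBm synthesis failed (non-positive-definite circulant embedding)."""
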