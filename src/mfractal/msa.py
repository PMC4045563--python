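"""Generalized Hurst spectrum estimation via structure functions.

For a signal :math:`S(t)` sampled at unit intervals, the q-th order
structure function at lag ``d`` is the normalized q-th absolute moment of
the increments,

.. math::

    K_q(d) = \\frac{\\langle |S(t+d) - S(t)|^q \\rangle_t}
                  {\\langle |S(t)|^q \\rangle_t},

where the numerator averages over the :math:`T-d` valid start points and
the denominator over all :math:`T` samples.  For a self-affine signal the
structure functions obey the scaling law :math:`K_q(d) \\propto d^{\\,qH(q)}`,
so the generalized Hurst exponent :math:`H(q)` is read off as
``slope / q`` from an ordinary least-squares fit of :math:`\\log K_q(d)`
against :math:`\\log d`.

``H(2)`` is the classic Hurst exponent: 0.5 for a random walk, above 0.5
for persistent signals, below 0.5 for antipersistent ones.  A monofractal
signal has H(q) constant in q; a multifractal one does not.  Evaluating
H(q) at the first six integer moments gives the six-component texture
feature vector used downstream for image classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mfractal.errors import (
    DegenerateSignalError,
    InsufficientLagsError,
    InvalidInputError,
    InvalidLagError,
)

DEFAULT_Q_VALUES: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
DEFAULT_D_MAX: int = 19


@dataclass(frozen=True)
class Signal1D:
    """A finite, real-valued signal S(t) sampled at unit intervals.

    Parameters
    ----------
    values
        Ordered samples S(1..T).  Stored as a read-only float64 array.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64).ravel()
        if arr.size < 2:
            raise InvalidInputError(
                f"signal needs at least 2 samples, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("signal contains non-finite values")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class StructureFunctionTable:
    """K_q(d) on a grid of moment orders q and lags d.

    ``K[i, j]`` holds :math:`K_{q_i}(d_j)`.  Entries are nonnegative by
    construction and invariant under rescaling of the signal by any
    nonzero constant (numerator and denominator both scale by |c|^q).
    """

    q_values: np.ndarray
    d_values: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=np.float64).ravel()
        d = np.asarray(self.d_values, dtype=np.int64).ravel()
        K = np.asarray(self.K, dtype=np.float64)
        if K.shape != (q.size, d.size):
            raise InvalidInputError(
                f"K has shape {K.shape}, expected {(q.size, d.size)}"
            )
        for arr in (q, d, K):
            arr.setflags(write=False)
        object.__setattr__(self, "q_values", q)
        object.__setattr__(self, "d_values", d)
        object.__setattr__(self, "K", K)


@dataclass(frozen=True)
class HurstSpectrum:
    """Estimated generalized Hurst exponents with regression diagnostics.

    ``H[i] == slope[i] / q_values[i]`` exactly, where ``slope[i]`` is the
    OLS slope of log K_q(d) on log d and ``r_squared[i]`` its coefficient
    of determination.  ``H`` is the feature vector consumed by the
    classifier.
    """

    q_values: np.ndarray
    H: np.ndarray
    slope: np.ndarray
    r_squared: np.ndarray

    def __post_init__(self) -> None:
        for name in ("q_values", "H", "slope", "r_squared"):
            arr = np.asarray(getattr(self, name), dtype=np.float64).ravel()
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        n = self.q_values.size
        if not (self.H.size == self.slope.size == self.r_squared.size == n):
            raise InvalidInputError("spectrum fields must have equal length")


def _as_signal(signal: Signal1D | np.ndarray) -> Signal1D:
    return signal if isinstance(signal, Signal1D) else Signal1D(np.asarray(signal))


def structure_function(
    signal: Signal1D | np.ndarray, q: float, d: int
) -> float:
    """Compute the q-th order structure function K_q(d) of a signal.

    Parameters
    ----------
    signal
        The input signal (T samples); must not be identically zero.
    q
        Moment order, q > 0.
    d
        Lag in samples, 1 <= d <= T-1.

    Returns
    -------
    float
        Mean of |S(t+d)-S(t)|^q over the T-d valid start points, divided
        by the mean of |S(t)|^q over all T samples.

    Raises
    ------
    InvalidLagError
        If ``d`` is not in [1, T-1].
    DegenerateSignalError
        If the signal is identically zero (denominator vanishes).
    """
    sig = _as_signal(signal)
    s = sig.values
    T = s.size
    if q <= 0:
        raise InvalidInputError(f"moment order q must be positive, got {q}")
    d = int(d)
    if not 1 <= d <= T - 1:
        raise InvalidLagError(f"lag d={d} outside valid range [1, {T - 1}]")
    denom = np.mean(np.abs(s) ** q)
    if denom == 0.0:
        raise DegenerateSignalError("signal is identically zero")
    numer = np.mean(np.abs(s[d:] - s[:-d]) ** q)
    return float(numer / denom)


def structure_function_table(
    signal: Signal1D | np.ndarray,
    q_values: "np.ndarray | tuple[float, ...]" = DEFAULT_Q_VALUES,
    d_max: int = DEFAULT_D_MAX,
) -> StructureFunctionTable:
    """Tabulate K_q(d) for every q in ``q_values`` and d in 1..d_max.

    One vectorized pass per lag computes all moment orders at once; the
    result agrees entrywise with repeated :func:`structure_function`
    calls.

    Raises
    ------
    InvalidLagError
        If ``d_max > T - 2`` (at least two increments are required at the
        largest lag and at least two lags for the downstream regression).
    DegenerateSignalError
        If the signal is identically zero.
    """
    sig = _as_signal(signal)
    s = sig.values
    T = s.size
    q = np.asarray(q_values, dtype=np.float64).ravel()
    if q.size == 0 or np.any(q <= 0):
        raise InvalidInputError("q_values must be a nonempty list of positive reals")
    d_max = int(d_max)
    if d_max < 1:
        raise InvalidLagError(f"d_max must be >= 1, got {d_max}")
    if d_max > T - 2:
        raise InvalidLagError(
            f"d_max={d_max} too large for signal of length {T} (need T >= d_max + 2)"
        )
    abs_s = np.abs(s)
    denom = np.mean(abs_s[None, :] ** q[:, None], axis=1)  # per q
    if np.any(denom == 0.0):
        raise DegenerateSignalError("signal is identically zero")
    d_values = np.arange(1, d_max + 1, dtype=np.int64)
    K = np.empty((q.size, d_values.size), dtype=np.float64)
    for j, d in enumerate(d_values):
        incr = np.abs(s[d:] - s[:-d])
        K[:, j] = np.mean(incr[None, :] ** q[:, None], axis=1) / denom
    return StructureFunctionTable(q_values=q, d_values=d_values, K=K)


def estimate_hurst(table: StructureFunctionTable) -> HurstSpectrum:
    """Estimate the generalized Hurst spectrum from a structure-function table.

    For each moment order q an ordinary least-squares line is fitted to
    log K_q(d) versus log d over all tabulated lags with equal weight;
    H(q) is the fitted slope divided by q.  Natural logarithms are used
    (the slope, hence H, is base-independent).

    Raises
    ------
    InsufficientLagsError
        If the table has fewer than two distinct lags.
    DegenerateSignalError
        If any K_q(d) entry is zero (logarithm undefined); the error
        names the offending (q, d).
    """
    if np.unique(table.d_values).size < 2:
        raise InsufficientLagsError(
            "need at least 2 distinct lags for the log-log regression"
        )
    zero = np.argwhere(table.K == 0.0)
    if zero.size:
        i, j = zero[0]
        raise DegenerateSignalError(
            f"K_q(d) = 0 at q={table.q_values[i]:g}, d={table.d_values[j]}; "
            "log-log regression undefined"
        )
    log_d = np.log(table.d_values.astype(np.float64))
    n_q = table.q_values.size
    H = np.empty(n_q)
    slope = np.empty(n_q)
    r2 = np.empty(n_q)
    for i, q in enumerate(table.q_values):
        fit = stats.linregress(log_d, np.log(table.K[i]))
        slope[i] = fit.slope
        H[i] = fit.slope / q
        r2[i] = fit.rvalue**2
    return HurstSpectrum(q_values=table.q_values, H=H, slope=slope, r_squared=r2)


def hurst_spectrum(
    signal: Signal1D | np.ndarray,
    q_values: "np.ndarray | tuple[float, ...]" = DEFAULT_Q_VALUES,
    d_max: int = DEFAULT_D_MAX,
) -> HurstSpectrum:
    """Convenience composition: structure-function table then Hurst fit."""
    return estimate_hurst(structure_function_table(signal, q_values, d_max))
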