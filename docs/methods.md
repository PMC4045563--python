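# Methods

## Structure-function Hurst estimation

For a discrete signal `S(t)`, `t = 1..T`, sampled at unit intervals, the
q-th order structure function at lag `d` is

    K_q(d) = [ (1/(T−d)) Σ_{t=1}^{T−d} |S(t+d) − S(t)|^q ]
             / [ (1/T) Σ_{t=1}^{T} |S(t)|^q ] .

The numerator is the sliding-window (full-overlap) average of absolute
increments raised to the q-th power; the denominator normalizes by the
q-th absolute moment of the signal itself, which makes `K_q(d)` exactly
invariant under multiplication of the signal by any nonzero constant —
both parts scale by `|c|^q`. Absolute values make the moments
well-defined for odd and non-integer q.

For a self-affine signal `K_q(d) ∝ d^{qH(q)}`. `H(q)` is estimated per
q by ordinary least squares of `log K_q(d)` on `log d` over all lags
`d = 1..d_max` with equal weight; natural logarithms are used (the
slope, hence H, is base-independent), and the per-q coefficient of
determination r² is kept as a diagnostic. `H(q) = slope/q` holds by
construction. A constant `H(q)` across q indicates a monofractal
signal; variation with q indicates multifractality. `H(2)` is the
classic Hurst exponent (0.5 for a random walk).

Assumptions: unit sampling interval (pixels are unit-spaced); the
scaling law holds across the fitted lag range. No log-spaced lag
subsampling, no weighting, no bias correction for short signals — the
estimator enforces `T ≥ d_max + 2` instead and otherwise fits plainly.
A zero structure-function entry (e.g. a constant signal) aborts
estimation with an error naming the offending `(q, d)` rather than
silently dropping lags, because dropping would change the regression
support invisibly.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `q_values` | 1..6 | moment orders; six integer moments give the feature vector |
| `d_max`    | 19   | largest lag; regression support is d = 1..19 |

Both are exposed everywhere. Negative/continuous q (full multifractal
formalism), wavelet-leader and MF-DFA estimators, and 2D box-based
fractal dimensions are out of scope.

## Image handling

Images (PNG/TIFF/JPEG, 8- or 16-bit) are collapsed to grayscale with
BT.601 luminance weights if multi-channel, converted to doubles in
[0, 1] by dividing by the full-scale value `2^depth − 1`, and flattened
to 1D by row concatenation: element `r·W + c` is the pixel at row r,
column c, rows top to bottom. The orientation is fixed and documented
for reproducibility; "row concatenation" alone does not determine it.
No masking, cropping or segmentation is applied — the method is
deliberately global, trading anatomical specificity for simplicity and
speed. Because `K_q(d)` is scale-invariant, the [0, 1] normalization
does not affect the features; it is kept for a well-defined numeric
contract.

Row concatenation introduces artificial jumps at row boundaries; with
`d_max = 19` far below the row width (≥ 32, typically 128–256), these
contribute a vanishing fraction of increment terms.

## Classification

Two-class soft-margin SVM with the inhomogeneous polynomial kernel
`K(x, y) = (x·y + 1)^degree`. The dual quadratic program is solved by
scikit-learn's SVC (gamma = 1, coef0 = 1, so the kernel is exactly the
form above); the fitted model is stored as support vectors, multipliers
`α_i > 0`, labels `y_i` and bias `b`, and predictions are evaluated
in-package as `sign(Σ_i y_i α_i K(x, x_i) + b)`. A decision value of
exactly 0 maps to the negative class — a fixed, documented tie-break,
with no claim that this is the clinically conservative direction. The
dual constraints `Σ α_i y_i = 0` and `0 ≤ α_i ≤ C` are asserted in
tests on every trained model, and the in-package kernel expansion is
cross-checked against the backend's decision function.

Defaults: degree 4 (degrees 2–4 supported; 4 is where the reference
experiments performed best), `C = 1.0` (conventional; reported results
should state it), standardization on. Features are z-scored with
location/scale estimated from the training data only and stored in the
model; polynomial kernels are scale-sensitive across features of
different magnitudes, and computing the transform inside each
cross-validation fold avoids leaking the held-out sample. With a
constant feature the scale falls back to 1 (centering only).

Leave-one-out cross-validation predicts each sample from a model
trained on the remaining n−1. Metrics over held-out predictions: CCR =
correct/total; sensitivity = correct rate among positives (+1);
specificity = correct rate among negatives (−1). The `±` dispersions
are the sample standard deviations (ddof = 1) of the per-fold 0/1
correctness indicators, overall and within each class — one defensible
convention for attaching a spread to LOOCV point metrics, stated here
because it is a convention, not a theorem.

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

- **Random walk** — cumulative sum of i.i.d. ±1 steps; `H = 0.5`
  exactly in expectation. The canonical null case.
- **fBm** — fractional Gaussian noise synthesized by circulant
  embedding (Davies–Harte): the fGn autocovariance
  `γ(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2` is embedded in a
  circulant of order 2T, whose eigenvalues (FFT of the first row) are
  nonnegative for H ∈ (0, 1); scaled complex Gaussians transformed by
  FFT give a sample with the exact target covariance, accumulated into
  fBm. Exact synthesis was chosen over midpoint displacement because
  parameter-recovery tests need unbiased ground truth. Lengths are
  restricted to powers of two ≥ 1024 (FFT convenience; keeps the
  embedding well-conditioned). Eigenvalues below −1e-8 raise a
  synthesis error; tiny negatives from roundoff are clipped to zero.
- **Textures** — 2D spectral synthesis: white complex Gaussian noise
  shaped by a radial power-law amplitude filter `f^−(roughness+1)`
  (the spectral signature of a self-affine surface with Hurst exponent
  ≈ roughness), inverse-FFT'd and min-max rescaled to [0, 1]. Simpler
  and faster than exact 2D fBm, and sufficient for a controlled
  between-class contrast. Default size 128×128 (T = 16384 per image,
  comfortably above what d_max = 19 needs).
- **Two-class dataset** — default 20 images per class with class
  roughness (0.7 for the positive/"smoother" class, 0.3 for the
  negative): pilot calibration placed default LOOCV accuracy in the
  0.95–1.0 band, mirroring a near-perfect-classification regime without
  overclaiming. Per-image seeds are spawned deterministically from the
  dataset seed, so a dataset is a pure function of (parameters, seed).

What the synthetic data does *not* emulate: brain anatomy, disease
pathology, MRI noise and intensity inhomogeneity, scanner variability.
Passing tests therefore demonstrate that the estimator recovers known
scaling exponents and that the pipeline separates classes that differ
in fractal roughness — not that any particular clinical accuracy would
be attained on real images.

## Numerical notes

- Structure-function evaluation is vectorized (one pass per lag, all q
  at once) and verified against a brute-force double loop at relative
  1e-12.
- The ramp `S(t) = t` is an exact analytic case: increments at lag d
  all equal d, so `K_q(d) = d^q / ⟨t^q⟩`, giving `H(q) = 1` and
  `r² = 1` to machine precision.
- Scale invariance of the features is exact in exact arithmetic; in
  doubles the scaled input pixels are themselves rounded, so observed
  feature differences are at the 1e-17 level (bit-exact for power-of-
  two factors that skip renormalization).
- Problem sizes used in the validation suite — signals of T = 65536
  (the row-concatenated length of a 256×256 image), 20 realizations per
  condition, 20 images per class at 128×128 — keep every check well
  inside a desktop-scale run while leaving estimator standard errors
  far below the tolerances being asserted.

## Known limitations

- Six integer moments only; no negative-q branch of the multifractal
  spectrum.
- OLS on log-log values has no per-lag error weighting; for strongly
  multifractal or short signals, fit diagnostics (r²) should be
  inspected.
- LOOCV dispersion convention (per-fold indicator SD) is one reading of
  "± spread under LOOCV"; alternatives (e.g. repeated k-fold) would
  give different spreads.
- The texture generator's roughness is an approximate, not exact, Hurst
  parameter for the resulting surface; class separation, not exact 2D
  parameter recovery, is its design goal.
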