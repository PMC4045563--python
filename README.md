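# mfractal

Multiscale fractal analysis of grayscale images and 1D signals, with a
polynomial-kernel SVM classifier on the resulting Hurst-spectrum
features.

The package targets texture-based discrimination of medical images —
the motivating case is separating healthy from Alzheimer's-affected
axial T2-weighted brain MRI slices — where global image texture, not a
segmented region, carries the diagnostic signal. Because the feature
extraction needs no registration, masking or segmentation, it also
applies to any setting where two image populations differ in the
roughness/persistence structure of their intensity fluctuations.

## Method

An image is flattened to a 1D signal `S(t)`, `t = 1..T`, by row
concatenation (a 256×256 image gives `T = 65536`). For each moment
order `q` and lag `d`, the normalized structure function is

```
K_q(d) = ⟨ |S(t+d) − S(t)|^q ⟩_t  /  ⟨ |S(t)|^q ⟩_t ,
```

with the numerator averaged over the `T − d` valid start points and the
denominator over all `T` samples. For a self-affine signal
`K_q(d) ∝ d^{qH(q)}`, so the generalized Hurst exponent `H(q)` is
`slope/q` from an OLS fit of `log K_q(d)` against `log d` over
`d = 1..19`. `H(2)` is the classic Hurst exponent: 0.5 for a random
walk, above 0.5 for persistent signals, below for antipersistent ones.
The vector `(H(1), …, H(6))` is the image's feature descriptor.

Classification uses a soft-margin SVM with the inhomogeneous polynomial
kernel `K(x, y) = (x·y + 1)^degree` (default degree 4, `C = 1`,
features z-scored from the training split). Performance is evaluated by
leave-one-out cross-validation, reporting CCR (correct classification
rate), sensitivity (correct rate among positives) and specificity
(correct rate among negatives).

A synthetic-data module supplies ground truth for every stage: ±1
random walks (`H = 0.5` by construction), exact fractional Brownian
motion via circulant-embedding synthesis (prescribed Hurst parameter),
and two-class 2D fractal textures generated by spectral synthesis whose
roughness contrast mimics the between-class texture difference in real
MRI.

## Worked example

`examples/03_classify_textures.py` runs the whole pipeline on synthetic
data — 20 images per class, Hurst features, degree-4 kernel, LOOCV:

```
CCR         = 1.0000 +/- 0.0000
sensitivity = 1.0000
specificity = 1.0000
misclassified folds: none
```

All 40 held-out predictions are correct: at the generator's default
class contrast the two texture classes are cleanly separable in
`H(1..6)` space. `examples/01_hurst_of_a_signal.py` shows parameter
recovery on simulated fBm with `H = 0.7`:

```
q    H(q)    r^2
1  0.6943  0.99998
2  0.6927  0.99998
...
6  0.6891  0.99998
```

`H(2) = 0.693` sits within sampling error of the generating value, the
near-flat profile across q is the monofractal signature of fBm, and
`r² ≈ 1` confirms the power-law scaling the estimator assumes.

## Command line

```
mfractal simulate dataset --seed 0 --out features.csv
mfractal evaluate --features features.csv --degree 4 --out report.json
mfractal extract --images DIR --out features.csv
mfractal analyze-signal --signal sig.csv --out spectrum.csv
```

Every command writes a `*.manifest.json` capturing its full
configuration and seed, so any output can be regenerated.

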