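"""Turn a grayscale image into a six-component fractal feature vector.

Generates a 2D fractal texture, flattens it to a 1D signal by row
concatenation, and reads off H(1..6) — the texture descriptor used for
classification.  Rougher textures (lower spectral roughness) give lower
Hurst exponents.
"""

from mfractal import TextureSpec, extract_features, generate_texture

for roughness in (0.3, 0.7):
    image = generate_texture(
        TextureSpec(height=128, width=128, roughness=roughness, seed=1)
    )
    spectrum = extract_features(image)
    feats = "  ".join(f"{h:.3f}" for h in spectrum.H)
    print(f"roughness={roughness}:  H(1..6) = {feats}")

# The two rows are the feature vectors an SVM would see for one image of
# each class: the smoother (roughness 0.7) surface scores visibly higher
# H(q) at every order q.
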