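# Methods

This note records the model implemented by `swirclass`, the parameter
defaults and why they were chosen, the scope and limits of the synthetic
study generator, and the numerical analysis behind the package's exactness
claims.

## 1. Forward optical model (`swirclass.spectral`)

The signal recorded through one long-pass filter is

```
S_f = ∫ T_f(λ) · QE(λ) · E_em(λ) dλ
```

with `T_f` the filter transmission, `QE` the sensor quantum efficiency and
`E_em` the fluorophore emission spectrum. All curves are tabulated
wavelength/value pairs, linearly interpolated inside their support and zero
outside.

**Emission reconstruction.** Published emission curves of NIR-I dyes were
measured with silicon detectors and miss the SWIR tail. The full curve is
reconstructed by the Franck–Condon mirror-image rule: the absorption
spectrum is reflected about the 0–0 transition wavelength `λ₀`
(`λ → 2λ₀ − λ`), rescaled by a single least-squares factor to match a
measured SWIR tail on their overlap, stitched at the overlap midpoint
(mirror below, tail above) and normalized to a peak of 1. A missing overlap
is an error, not a silent extrapolation.

**Quadrature.** Integrals use the trapezoid rule on a uniform grid (default
1 nm) *unioned with every tabulation knot* of the three input curves.
Because the integrand is piecewise linear between nodes whenever at most one
factor varies there, box-emission/step-filter cases integrate exactly.
Ideal step filters are modeled as symmetric linear ramps of half-width
10⁻⁶ nm about the cut-off, whose trapezoid integral equals the true step
integral once the ramp knots are on the grid. Smooth default curves agree
with a 0.1 nm midpoint-Riemann reference to better than 0.1 %.

**Defaults.** Cut-offs 850/950/1050/1150/1250/1350 nm; logistic filter
edges (plateau 0.98, 10–90 % width 10 nm); InGaAs-like QE (0.85 plateau
over ~950–1600 nm with soft roll-offs); a schematic NIR-I dye emission
(Gaussian peak at 800 nm plus a broad SWIR tail). The shipped curves are
parameterized stand-ins for data-book curves and can be replaced from
two-column CSV files.

## 2. Cube assembly (`swirclass.cube`)

Raw 16-bit frames are acquired per filter over an exposure ladder. For each
filter the *longest exposure with zero pixels above the saturation
threshold* (default 35 000 counts, strict `>`) is kept; if every rung
saturates, the frame with the fewest saturated pixels wins (ties toward the
shorter exposure) and the count is logged. The channel is then
`max(signal − dark, 0) / exposure`, giving counts/s; a dark frame with
matching exposure is used when available, otherwise the log-nearest dark is
scaled linearly by the exposure ratio. Channels stack in ascending cut-off
order.

Band images (for visualization) are consecutive-channel differences;
negative pixels are retained, so bands plus the last channel telescope back
to the first channel.

`apply_exposure_factor` multiplies a cube by a scalar `E` summarizing
working distance, illumination, exposure time and dose. Deliberately, no
re-quantization or clipping is applied: the factor models post-hoc radiance
rescaling, which is the regime in which the invariance claim below is an
identity.

## 3. Preprocessing (`swirclass.preprocess`)

Row-wise spectrum normalizations: `none`; `max` (divide by the row maximum);
`auc` (divide by the row sum); `snv` (subtract the row mean, divide by the
sample standard deviation, `ddof = 1`). Degenerate rows (zero max / sum /
variance — legitimately produced by dark background pixels) map to the
all-zero row and are flagged, keeping per-pixel classification total.
Normalizing a single-channel spectrum is refused: with one wavelength there
is no spectral shape to normalize, which is exactly why the mono condition
in the robustness study cannot be rescued by normalization.

ROIs are a single integer label map (0 unlabeled, 1 tumor, 2 non-tumor
tissue, 3 background), making the classes mutually exclusive by
construction. Line profiles average `width_px` (default 3, odd) parallel
single-pixel lines with bilinear interpolation.

## 4. Classifiers (`swirclass.classify`)

Seven configurations: {PCA, SAM} × {LDA, KNN} plus SAM-min, NN and PCA-NN.

* **PCA** is implemented in-package (eigendecomposition of the sample
  covariance) because the package fixes a deterministic sign convention —
  the largest-magnitude element of each loading column is made positive —
  that scikit-learn's `svd_flip` does not honor; scikit-learn PCA is used as
  an independent cross-check in the tests. Truncation to the first 4/5/6
  PCs is the studied grid (default 4).
* **SAM** features are the angles `arccos(⟨x, r_c⟩ / (|x||r_c|))` to the
  three per-class mean training spectra (cosines clipped to [−1, 1]).
  All-zero rows get π/2 to every class and are flagged; `SAM-min` assigns
  them to background (a zero spectrum is a dark pixel).
* **KNN** (k = 5) is implemented in-package because the tie-break rule is
  part of the method's specification: majority vote, vote ties broken
  toward the class with the nearer mean neighbor distance, remaining ties
  toward the lower class label; neighbor-distance ties resolve toward the
  earlier training row (stable sort). A brute-force restatement of this
  rule serves as the oracle in the tests.
* **LDA** uses scikit-learn's SVD solver, which handles the singular
  within-class covariances produced by normalized spectra through its own
  tolerance (a deviation from a pooled-covariance + fixed-ridge variant
  considered during design; the SVD solver is better conditioned and
  standard).
* **NN** is scikit-learn's `MLPClassifier` (one hidden layer of 10 logistic
  units, lbfgs) trained in short warm-start rounds with early stopping on a
  held-out validation cube: the best-validation snapshot is kept and
  training stops after 6 rounds without improvement. Inputs are min-max
  scaled to [−1, 1] with train-set statistics.

**Evaluation protocol.** Train on one image cube, test pooled over the
rest; with four cubes this yields four permutations. Overall and per-class
accuracies are averaged over permutations, confusion matrices are summed.
The network methods hold out the next cube in cyclic order for validation
and test on the remaining two. Feature pipelines (PCA mean/loadings, SAM
references, NN scaling) are functions of the training cube alone.

## 5. Exposure robustness (`swirclass.robustness`)

For `E > 0` and any row `x`, `max/auc/snv` satisfy `n(E·x) = n(x)` in real
arithmetic — the scalar cancels — so a classifier consuming normalized
spectra produces *pixel-identical label maps* for `E·cube` and `cube`. In
floating point the normalized rows can differ in the last ulp, which could
in principle flip an exact distance tie; the tests verify bitwise equality
empirically across methods, normalizations and `E ∈ {0.1 … 10}`. The
contrasted conditions are `mono` (lowest cut-off channel only, 1 PC, no
normalization possible), `multi_unnormalized`, and `multi_auc`; the default
grid is `E ∈ {0.1, 0.25, 0.5, 1, 2, 4, 10}`.

## 6. Synthetic study generator (`swirclass.phantom`)

The generator reproduces the statistical structure the classifier relies
on, not photon transport:

* **Scene.** An elliptical body; a tumor ellipse emitting the pure
  endmember (the L1-normalized 6-filter forward-model signal, which is
  strictly decreasing across cut-offs because long-pass filters nest);
  tissue and optional liver-/femur-like off-target blobs emitting the
  *colored* endmember `s · exp(−σ·w)` with `w` a water-absorption weight
  shape concentrated in the 1150–1350 nm channels; a Gaussian scatter halo
  around sources.
* **Calibrated contrast.** The coloring strength `σ` is solved (Brent's
  method) so the tumor/tissue endmember spectral angle is 4° — a subtle,
  shape-only difference. Tumor and tissue brightnesses are *overlapping*
  lognormals (medians 6000 vs 2000 counts/s, log-sd 0.30), so intensity
  thresholds cannot survive exposure changes; the off-target median (9000,
  log-sd 0.4) is bright enough to saturate the 5 s rung and exercise
  exposure selection. These defaults were calibrated once, when the
  generator was designed, so that the intended contrasts (shape separable,
  intensity not; mono collapses under a 10× exposure change) exist at the
  reduced 160×128 study size, and then frozen.
* **Individuals.** Per-individual lognormal endmember jitter (cv = 0.02 —
  spectra are conserved between individuals) and a decreasing global
  brightness sequence (1.0, 0.75, 0.55, 0.40) emulating time since
  injection. Negative-control individuals have zero fluorophore radiance.
* **Sensor.** Exposure ladder 0.01–5 s; counts =
  `round(Poisson(radiance·t) + 100 + N(0, 10))`, clipped at 65 535. Shot
  noise, read noise, dark offset and quantization are all independently
  switchable.
* **Seeding.** Every stream derives from
  `default_rng([seed, individual_id, stream])`; identical configurations
  reproduce byte-identical frames.
* **Degenerate variants.** `noiseless_config` (no noise, no offset, no
  quantization) supports exact round-trip checks; `negative_control_config`
  (coloring ≡ 1, tissue/off-target brightness distributions equal to the
  tumor's) removes all class structure except background darkness — the
  package's negative control, on which tumor-vs-tissue accuracy collapses
  to chance.

**Limits.** No photon transport, no depth dependence, no autofluorescence
spectra, no spatial texture beyond the halo; brightness fields are
pixelwise independent. The generator is a test instrument, not a tissue
model.

## 7. Numerical exactness

Three different strengths of claim appear in the tests:

* **Exact by construction** (bitwise): box/step quadrature (piecewise-linear
  integrand on the knot-unioned grid); exposure-invariance of normalized
  label maps (empirically bitwise; ulp-level caveat above).
* **Exact in IEEE arithmetic under restrictions.** The acquisition
  round-trip `scene → ladder → select → dark-subtract → divide by exposure`
  is bitwise only when no rounding occurs: noiseless sensor, zero dark
  offset, quantization off, and unit or power-of-two exposures (division is
  then exact). Band-image telescoping is bitwise on integer-valued channels
  (quantized counts at unit exposure: all float64 operations on integers
  below 2⁵³ are exact); generic float channels telescope to ~10⁻¹³
  relative and are tested with tolerances.
* **Tolerance-based**: smooth-curve quadrature vs a 0.1 nm reference
  (≤ 0.1 %); vectorized-vs-scalar SAM angles (≤ 10⁻¹², BLAS product vs
  per-pair dot differ in the last ulp).

## 8. External interfaces

Raw acquisitions: one 16-bit TIFF per (filter, exposure) frame plus a
`manifest.csv`. Cubes: multi-page float32 TIFF plus JSON sidecar
(cut-offs, chosen exposures, exposure factor, provenance). Masks: integer
TIFF/PNG. Label maps: indexed PNG with a fixed 4-color palette. Phantom
configs: YAML. Trained classifiers: a single joblib archive with a
self-describing header (`method`, `normalization`, `k`, `hidden_units`,
`seed`, `n_retained`, training cube id) — a deviation from a JSON + raw
binary layout considered during design, because the scikit-learn inner
models are not losslessly JSON-serializable.

CLI: `swirclass simulate | build | classify | grid | sweep`; exit code 2
for configuration errors, 3 for data errors; one `--seed` drives all
randomness.
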