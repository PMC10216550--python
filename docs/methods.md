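# Methods

This note documents the models and procedures implemented in `ppsw`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Periodic-plus-smooth decomposition

A discrete image `u` on an M×N grid is split as `u = p + s`. The smooth
component solves the periodic discrete Poisson-like system `Δ_per s = v`,
where `v` accumulates the differences between opposite borders (first/last
rows: `u(M−1−y, x) − u(y, x)`; first/last columns analogously; corner
pixels accumulate both contributions). In the Fourier domain

    ŝ(q, r) = v̂(q, r) / (2 cos(2πq/M) + 2 cos(2πr/N) − 4),   ŝ(0,0) = 0,

and `p = u − s`. Because `v` is real and the operator symmetric, the
inverse transform of `ŝ` is real up to round-off; the implementation
asserts the imaginary residue is below 1e−8 of the dynamic range before
discarding it. Consequences verified by construction and by test:

* `p + s = u` to 1e−9 of the range (exact additivity);
* `mean(s) = 0`, so `p` carries the image mean;
* the 5-point Laplacian of `s` vanishes at interior pixels (harmonicity);
* `p` has matching opposite borders, so the cross-shaped artifact that a
  non-periodic image imprints on the frequency axes of its DFT is strongly
  reduced (asserted as an axis-energy inequality on ramp images).

Images are processed in double precision with no rescaling: the
decomposition is linear, so intensity scaling is deferred to feature
extraction.

The DFT-modulus transform used downstream is `log(1 + |F(u)|)` with
quadrants swapped so the zero frequency is central. `log1p` rather than a
bare logarithm keeps the transform defined at spectral zeros.

## Wavelet illumination correction

Restoration needs an estimate of the multiplicative shading field.  Both
components are analyzed with a separable 2-D multi-level DWT (default
`bior1.1`, level 5, symmetric half-sample extension; `bior1.1` at level 5
is the configuration that won the classification-driven selection among
biorthogonal/Coiflet/Daubechies/Symlet candidates, and the sweep utility
reproduces that selection loop on synthetic data).  The fusion rule —
deliberately isolated in `illumination_estimate` so alternatives can be
swapped — keeps only slowly varying content:

    b = recon(approx_L(s))  +  (recon(approx_L(p)) − mean(u))
    corrected = u − b + mean(b)

Rationale: vignetting is low-frequency; the smooth component carries the
border-induced trend and the coarse approximation of `p` the interior
shading. Subtracting both while restoring the global mean flattens the
background without touching cell-scale detail. Properties that follow:

* `mean(corrected) = mean(u)` exactly (float path);
* a constant image is a fixed point, and a scene with flat illumination is
  nearly one (≥ 40 dB PSNR against the input on a background-only scene);
* applying the correction twice changes almost nothing (the re-estimated
  `b` of a corrected image is nearly constant);
* on vignetted synthetic scenes the background coefficient of variation
  drops, and the estimated field correlates > 0.9 with the generator's
  ground-truth vignette.

The float output is the exact corrected field; clipping to
`[0, 2^bit_depth − 1]` and rounding happen only when an integer image is
requested, because clipping necessarily breaks exact mean preservation on
out-of-range excursions.

Level 5 on the default 192×256 scenes leaves a 6×8 coarsest approximation,
i.e. the illumination model has ~50 degrees of freedom — smooth enough to
spare cell-scale structure. With dense cell cover some coarse-scale cell
mass inevitably leaks into `b`; this is inherent to any low-pass
illumination estimate and is why the near-identity check uses a
background-only scene.

## Robust PCA baseline

Principal component pursuit, `min ‖L‖* + λ‖S‖₁ s.t. L + S = M`, solved by
inexact augmented Lagrange multipliers: singular-value thresholding on L,
soft thresholding on S, penalty µ growing by 1.5 per iteration, default
`λ = 1/√max(M,N)`, tolerance 1e−7 on the relative Frobenius feasibility
residual, 1000 iterations max. Non-convergence is flagged on the result,
not raised. Note that the plain objective `‖L‖* + λ‖S‖₁` of IALM iterates
is *not* monotone — early iterates are infeasible and the objective grows
toward the converged value — so the solver logs both the objective and the
feasibility-residual traces; monotonicity holds for the latter. A strided
downscale path (nearest-neighbor upsampling of the result) is provided
because per-image SVDs at full frame size are the method's known cost
problem.

## Texture features

GLCMs are computed for distances 1–5 and orientations 0°, 45°, 90° (15
offsets), symmetrized and normalized; six Haralick statistics per matrix —
ASM, contrast, correlation, dissimilarity, energy = √ASM, homogeneity —
give 90 features per image, kept as separate columns (no averaging over
offsets) so per-feature attribution remains meaningful. Conventions that
had to be fixed and are therefore documented and oracle-tested:

* displacement for θ = 0° is (0, +d); 90° is (−d, 0); 45° is (−d, +d)
  (up-right diagonal, rows increasing downward);
* quantization is linear min–max binning per image into G = 256 levels
  (G trades GLCM sparsity against cost; 256 suits 16-bit inputs and float
  spectra alike); a constant image maps to level 0;
* correlation is defined as 1 when a marginal deviation vanishes;
* DFT-modulus inputs are log1p-scaled and quadrant-centered before
  quantization.

## Classification and interpretation

Feature tables are split 70:30 by seeded random sampling (stratified by
default — the data are balanced by design and stratification preserves
that; a knob disables it). The model zoo: decision tree, random forest
(500 trees, unlimited depth), AdaBoost, gradient boosting, histogram
gradient boosting (300 rounds, learning rate 0.1), XGBoost, LightGBM.
No feature standardization and no cross-validation are applied anywhere;
metrics are accuracy and macro-averaged precision/recall/F1 in percent,
computed on the held-out rows only.

Attributions use an exact path-dependent Tree SHAP implementation written
for this package (`ppsw.treeshap`, numba-compiled): Shapley values of the
cover-weighted conditional-expectation game per tree, averaged over forest
members, in probability space. Local accuracy — base value plus summed
attributions equals `predict_proba` — holds to machine precision and is
asserted at 1e−6. The implementation is validated against a brute-force
Shapley enumeration over all feature subsets on small trees. Attributions
are only defined for probability-averaging ensembles (single trees,
random/extra forests); score-aggregating boosters are rejected rather than
silently explained in the wrong space.

The restoration-vs-baseline bias statistic compares two SHAP summaries
over the same samples: per class, the mean over samples of the
feature-averaged |φ| difference (A − B). Averaging runs features → samples,
per class; feature sets of the two variants may differ. Antisymmetry and
zero self-bias are exact.

Supervised clustering embeds per-sample SHAP vectors with UMAP (15
neighbors, min_dist 0.1, seeded). The per-class attribution rows are
concatenated (features × classes columns) by default, preserving all
class-discriminative structure; a mean-over-classes reduction is available
as a config switch. Cluster quality is scored as the silhouette of the 2-D
coordinates against the true labels.

## Synthetic scene generator

The generator emulates 16-bit bright-field frames of adherent cell
cultures; it exists so the pipeline can be exercised end to end with known
ground truth. Composition: `vignette × (background + texture + blobs)
+ artifacts + noise`, clipped and quantized. Defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| frame | 192 × 256 px, 16-bit | desk-scale stand-in for full-size frames |
| background | 0.60 of range | bright-field illumination level |
| blob count means | 15 / 40 / 80 | low/medium/high density classes (Poisson) |
| blob shape | radius 4–10 px, anisotropic Gaussian, darkening 12 % ± 30 % | cell-like bumps |
| media texture | correlation length 1.5 / 3 / 6 px, sd 4 % | class A/B/C filtered-noise field |
| vignette | strength 0.5, radial Gaussian, corners at 1 − strength | multiplicative shading |
| vignette jitter | ±20 % strength, ±8 % center offset | field-to-field nuisance variation |
| stripe | 1.5 % amplitude, period 20–60 px, random phase/angle | oriented sinusoid ("stripy ghost") |
| dust | Poisson(8) discs, r 2–5 px, −10 % | dark specks |
| flare | one off-center Gaussian, +8 %, σ ≈ ¼ frame | broad lens-flare brightening |
| noise | Gaussian sd 1 % + Poisson at 0.05 counts/intensity unit | sensor + shot noise |

The jitter matters: with a bit-identical vignette on every frame, shading
would be a fixed offset a classifier could absorb; the per-scene variation
makes illumination a genuine confound, as in a real screening system where
the field varies across wells and time. Every scene is bit-reproducible
from its config; the generator exposes its exact vignette field, blob
placement log and background mask for oracle checks.

What the generator does **not** model: optical PSF, defocus, fluorescence
channels, realistic cell morphology or confluency mechanics, spatial
correlation between artifacts and cell positions. Passing the directional
tests on this bed shows the pipeline's machinery behaves as designed under
a controlled illumination confound — not that the measured accuracy gains
transfer quantitatively to real microscope data.

## Problem sizes and determinism

The repeated-seed studies use 9 × 30 scenes of 192 × 256 px per master
seed, ten master seeds, default forests; these sizes give stable win
fractions for the directional claims (restored-spectrum features beat
raw-image features; SHAP-space embeddings beat raw-feature embeddings)
while keeping a full run inexpensive. All randomness flows from explicit
seeds — scene generation from per-image seeds derived off a master seed
via `SeedSequence`, splits/models/UMAP from stage seeds — so every figure
a run prints is reproducible bit for bit.

## Known limitations

* The fusion rule is one concrete reading of "fuse the decomposed
  components"; it is isolated behind a single function precisely because
  other readings (e.g. keeping part of `s`'s detail, or level-dependent
  weighting) are defensible.
* Path-dependent Tree SHAP explains the cover-weighted conditional game;
  attributions differ from interventional SHAP when features are strongly
  correlated.
* The rPCA baseline at full frame size is slow (per-iteration SVDs); the
  downscale path is an approximation, adequate for feature extraction but
  not for pixel-accurate sparse-support recovery.
* PSNR medians on synthetic scenes are not comparable to any particular
  instrument's values; only relative orderings between techniques are
  meaningful here.
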