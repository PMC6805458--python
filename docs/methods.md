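# Methods

This note records the scientific and numerical conventions behind `radsig`:
what each stage computes, the parameters that matter, and the choices made
where the underlying methodology leaves room.

## Preprocessing

Clinical T2 acquisitions are anisotropic (slice thickness of several mm), so
each volume/mask pair is brought to a common footing before texture analysis:

* **Z-normalization** over *all* voxels of the image (not the ROI only):
  `(x − mean) / sd` with the population (divisor-N) standard deviation. A
  constant volume is rejected (`degenerate intensity distribution`).
  Normalization is idempotent to 1e−9.
* **Isotropic resampling** to `target_spacing_mm` (default 1.0): trilinear
  interpolation for intensities, nearest-neighbour + re-binarization for
  masks, with grid-mode zoom semantics so the voxel grid keeps covering the
  original physical extent. Smooth convex ROIs conserve physical volume
  within 5%.
* **Order**: normalize → resample by default; the reverse is available via
  `preprocess_order="resample-first"` since the original processing order is
  ambiguous. Both are exposed, one is the documented default.

## Feature extraction (431 features)

The vector is assembled in a fixed, documented order: 14 first-order, 8
shape, 22 GLCM, 11 GLRLM on the original image, then 14 + 22 + 11 = 47
features per wavelet band × 8 bands. Shape features depend only on the mask
and are not recomputed per band — this is what makes the arithmetic
14 + 8 + 33 + 376 = 431 work.

Three names (Energy, Entropy, Variance) exist in both the first-order and
GLCM families. In the flat vector the first-order features keep the bare
name and the GLCM ones are qualified as e.g. `Entropy (GLCM)`; a wavelet
feature like `Entropy_LLL` is therefore always the first-order entropy of
that band, which matches how published glioma signatures label it.

* **First-order** (ROI intensities): Energy (Σx²), Entropy and Uniformity
  from an `n_bins` (default 32) equal-width histogram over the ROI range
  (log base 2, 0·log 0 ≡ 0), population moments; Pearson (non-excess)
  kurtosis; skewness/kurtosis of a constant region are 0 by convention.
* **Quantization** for texture: `n_bins` equal-width gray levels over
  [ROI min, ROI max]; the maximum maps to the top level; levels are 1-based;
  a constant ROI is an error. Wavelet bands are re-quantized with their own
  ROI range.
* **GLCM**: distance-1 voxel pairs over the 13 unique 3D offsets (26-
  connectivity modulo sign), both ends in the ROI, counted in both orders
  (symmetric), counts pooled over directions then normalized (`sum`
  aggregation; `mean` — per-direction normalization, then averaging — via
  config). The 22 Haralick-style features use base-2 logs; Correlation is 0
  when a marginal variance vanishes; Inverse Variance sums off-diagonal
  cells only.
* **GLRLM**: maximal runs of constant gray level along each of the 13
  directions; an out-of-ROI voxel breaks a run. Matrices are summed over
  directions; run-cover conservation (Σ length × count = ROI voxels) holds
  per direction. Run Percentage divides by (ROI voxels × 13) so it stays in
  (0, 1]. The 11 features follow the Galloway/Chu definitions.
* **Shape**: Volume = voxel count × voxel volume. Surface area comes from a
  marching-cubes mesh of the mask after a light Gaussian smoothing
  (σ = 0.8 voxels, iso-level 0.5): meshing the raw binary grid produces a
  staircase surface that overestimates a smooth boundary's area by ≈9%,
  while the smoothed iso-surface is within ≈2% for digital balls of radius
  ≥ 5 (masks too small to survive smoothing fall back to the raw mesh — a
  single voxel gets the octahedral area 1.73 mm²). Sphericity, the two
  compactness variants and spherical disproportion are the standard
  functions of (V, A); Maximum 3D Diameter is the largest center-to-center
  distance between boundary voxels in mm (0 for a single voxel).
* **Wavelet**: single-level undecimated (stationary) 3D transform with the
  Coiflet-1 analysis pair applied separably; filtering is correlation with
  the filter centered at tap `len(w)//2` under symmetric boundary
  extension. Filters are rescaled to unit DC gain on the low-pass branch, so
  the LLL band of a constant image is that constant and every H-containing
  band annihilates constants. Band letters map to axes in x, y, z order
  (axis 0 first).

## mRMR selection

Features are discretized into 3 equal-frequency bins by default (stable-sort
rank binning, so ties resolve by sample order); mutual information is the
plug-in estimate in bits. Greedy forward selection starts from the most
relevant feature and then maximizes relevance − mean redundancy (difference
criterion; quotient available). Ties break by score, then lexicographically
by feature name — the selection is a pure function of
(table, k, criterion, bins). k defaults to 9, the published signature size;
how that size was originally chosen is not documented, so k is an explicit
config value rather than something tuned internally.

The selection inherits invariance to strictly monotone feature transforms
from the equal-frequency binning. The MI estimator has positive bias at
small n (~(levels−1)²/(2n ln 2) bits), which is why a label-independent
feature's relevance only approaches 0 as n grows.

## Classifier

RBF-kernel SVM over the 9×9 grid gamma, cost ∈ {10⁻⁴ … 10⁴}, scored by
stratified, seeded 10-fold cross-validated AUC on training rows only, refit
on all training rows with the winner. Grid ties break toward smaller cost,
then smaller gamma (stronger regularization). Features are z-scored with
training-row statistics before the kernel — at cost 10⁻³ an RBF on raw
feature scales is degenerate, so standardization is on by default (and
disable-able). Decision scores are signed distances to the separating
surface, oriented positive toward the "high" class; negative optimal cutoffs
are therefore meaningful. Validation rows never enter standardization, fold
assignment, or the grid; the test suite checks this by shuffling validation
labels.

Serialized models (`model.json`) store support vectors, dual coefficients,
intercept, gamma/cost, standardization parameters and the full 81-row CV
grid; scoring after deserialization evaluates the RBF decision function
directly and matches the fitted estimator to 1e−10.

## Evaluation

* **AUC**: Mann–Whitney (rank) form, ties counting ½ — the probability a
  random positive outscores a random negative. Invariant to monotone score
  transforms; AUC(s) + AUC(−s) = 1.
* **Optimal cutoff**: thresholds are midpoints between consecutive distinct
  scores plus sentinels beyond the extremes ("score ≥ cutoff" calls
  positive); the Youden index J = sens + spec − 1 is maximized, ties going
  to the cutoff nearest the score median; closest-to-(0,1) is available. If
  no cutoff beats chance the result is flagged with a warning rather than
  re-oriented.
* **Correlations**: pairwise Pearson (Spearman via config) with two-sided
  p-values; constant features correlate 0 with p = 1 under a warning.
  Whether a published "mean ± sd" of pairwise correlations refers to signed
  or absolute coefficients is often ambiguous, so both summaries are always
  reported (`mean`/`sd` and `mean_abs`/`sd_abs`).
* **Cohort balance**: chi-square without continuity correction (configurable)
  for categorical covariates, two-sample equal-variance t-test for
  continuous ones, mirroring a baseline-characteristics table.

## Synthetic data: what it emulates and what it does not

**Phantom cohorts** reproduce the statistical shape of the study: 239
samples by default (160 training / 79 validation via a random 2:1 split
drawn independently of the labels, flooring the validation count) with the
overall low/high imbalance 90/239. Each phantom is Gaussian background
noise (sd 1) plus an ellipsoidal ROI (semi-axes uniform in 6–12 voxels at
48³) whose interior is a unit-variance smoothed Gaussian random field
riding on a +2 hyperintensity baseline. The class signal is textural, matching
the texture-dominated character of published VEGF signatures: the "high"
class gets a mean shift δ and a longer correlation length ℓ. Presets
(δ, ℓ_low, ℓ_high): null (0, 1.5, 1.5), moderate (0.5, 1.2, 1.8), strong
(1.0, 1.0, 2.0), chosen so that null is exactly exchangeable between
classes and strong is cleanly separable end to end. Default volumes are
48³ at 1 mm isotropic spacing (anisotropic spacing is available to
exercise resampling); ROI size varies per sample but carries no class
information by default.

Phantoms do **not** model MRI physics: no bias fields, Rician noise,
partial-volume effects, skull/anatomy, scanner heterogeneity, or
inter-rater segmentation variability. A green end-to-end test establishes
that the pipeline's information flow is correct (signal in → signal out,
null in → chance out, no leakage), not that real-cohort AUCs are
reproduced — the original patient data are not public, and the published
AUCs (≈0.74/0.70) are out of reach of any phantom by construction.

**Feature tables** plant `k_informative` (default 9 of 431) columns with a
standardized class mean difference `effect_size` (default 1.0) among
nuisance columns that are block-equicorrelated (ρ = 0.3, blocks of 10) to
mimic the strong within-family correlation of radiomic features.

## Numerical conventions and degenerate inputs

Logs are base 2 throughout with 0·log 0 ≡ 0. Degenerate GLCMs (single
nonzero cell) yield Entropy 0 / Energy 1 and Correlation 0. Single-voxel
ROIs: shape features are defined (diameter 0), texture matrices raise
informative errors (no co-occurring pair / constant region). All random
processes take explicit integer seeds; pipeline reports embed the full
config and its hash, and rerunning a config reproduces the report byte for
byte.

## Known limitations

* Exact per-feature equation provenance for the original 431-feature set is
  not publicly archived; definitions here follow the standard
  Haralick/Galloway/IBSI forms, with the GLCM aggregation mode and
  homogeneity-style variants documented above. Features agree with
  independent brute-force references to 1e−9, but a different upstream
  implementation could differ in convention.
* Surface area has no independent in-repo oracle (one mesher); it is
  validated against analytic sphere areas instead, and everything derived
  from (V, A) is cross-checked exactly.
* The mRMR implementation is the classic greedy discretized-MI algorithm;
  ensemble variants of mRMR found in some R packages use different internal
  estimators and can select different features on the same data.
* Acceptance-level cohort tests run at reduced scale (24³ phantoms, n = 81)
  to respect CPU budgets; generator defaults remain full scale.
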