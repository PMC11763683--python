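# Methods

This note records the models, conventions and design choices behind
`dxaradiomics`, and what the synthetic experiments do and do not show.

## Synthetic cohort model

The generator emulates spine DXA scans as exported by scanner software
with overlay annotations, because clinical datasets of this kind are not
publicly available.

**Geometry.** Images default to 300×280 px (height × width). The two
lateral spine contours are low-amplitude sinusoids (amplitude 3–6 px,
wavelength bounded so the per-row column step never exceeds one pixel,
keeping the trace 8-connected) around verticals at ~33% and ~67% of the
image width. Five horizontal divider segments bound the four lumbar
vertebrae; the first and last define the L1-top and L4-bottom rows of the
ROI. Contour pixels are written at grey value 0 and divider segments at
255; tissue is clamped to [1, 254], so annotation detection can never
collide with tissue values.

**Texture.** Trabecular tissue is a stationary Gaussian random field:
white noise smoothed with a Gaussian kernel, rescaled to mean 150 and SD
35. Each patient draws an individual kernel width σ from a normal
distribution with between-patient SD 0.35 px (truncated at 0.4). Healthy
patients centre at σ = 1.0; degraded patients at
σ = 1.0 + 0.35 · `texture_separation`. The separation parameter is
therefore an *effect size* (class shift in units of the between-patient
spread): at 0 the classes are identically distributed, and separability
grows smoothly with it. The default, 4.0, was calibrated so that a
benchmark on the default cohort lands in the performance band reported
for clinical TBS-labelled data (best F-scores around 0.85–0.95 for
oversampled training sets, lower for undersampled ones). Degraded bone is
the *coarser, more homogeneous* texture — larger correlation length,
less fine-scale variance at fixed total variance — which mirrors the
loss of fine trabecular structure.

**Cortical rim.** The five tissue columns just inside each contour are
floored at grey 140 and the soft-tissue background is capped at 120
(mean 60, SD 8). This mimics the bright cortical shell at the vertebral
edges of a real projection and makes the contour detector's
inward-brighter neighbourhood test hold structurally on every row rather
than merely in expectation.

**Labels.** Binary healthy/degraded only, the TBS-threshold semantics
(≤ 1.200 degraded, ≥ 1.350 healthy) serving as the labelling rule; the
intermediate "partially degraded" band is not generated. Cohort
composition defaults to 13% degraded; `round(n · fraction)` fixes the
count exactly. A feature-space shortcut (`generate_feature_cohort`)
produces two isotropic Gaussian clusters whose mean separation is
`class_shift` within-class SDs, for tests that do not need imaging.

**What the generator does not model:** DXA attenuation physics, scanner
noise spectra, anatomical shape variation beyond the sinusoidal contour,
inter-vertebral intensity differences, or the TBS variogram computation
itself. Tests passing on this generator demonstrate correctness of the
pipeline's algorithms and the qualitative behaviour of resampling under
controlled class overlap — not clinical performance.

## Segmentation

Coordinates are (row, column), 0-based, row 0 at top. The left contour
scan visits each row's zero-valued pixels from the left edge up to
(excluding) floor(width/2); a pixel is accepted when the mean of the 5
pixels to its right exceeds the mean of the 5 to its left (window
truncated at borders; ties rejected) and when it is 8-connected to the
pixel accepted on the immediately preceding row (waived for the first
accepted row). The right contour mirrors from the right edge. Divider
rows are the first row from the top and the first from the bottom
containing a run of ≥ 10 pixels at the maximum representable grey value;
shorter runs are rejected as speckle. Both window width and minimum
segment length are configurable. The mask is the contour and divider
boundary plus a 4-connected flood fill seeded at the centroid of the
bounding rectangle; a fill that reaches the image border raises
`MaskNotClosed`. The algorithm is rule-based and exact: on clean
annotated input the mask equals the ground truth pixel for pixel, and the
test suite asserts Jaccard = 1.0 with no tolerance.

## Feature extraction

Discretisation is equal-width binning into a fixed number of levels
(default 32) between the ROI minimum and maximum; a constant ROI maps to
level 1. First-order Entropy and Uniformity reuse this discretisation so
a single setting governs the whole signature. Analysis is strictly 2D:
distance-1 offsets in four directions for GLCM/GLRLM with features
averaged over angles; GLSZM zones are 8-connected; GLDM uses α = 0,
δ = 1 with the dependence index defined as (dependent neighbours) + 1;
NGTDM uses δ = 1. Degenerate conventions: 0·log 0 = 0 throughout,
correlation of a constant ROI is 1, NGTDM coarseness is capped at 1e6
when its denominator vanishes, and NGTDM contrast/busyness/complexity/
strength are 0 when only one grey level is occupied. Pixel area is taken
as 1 (TotalEnergy = Energy): planar DXA exports carry no trusted spacing
here. Shape features are deliberately excluded — mask geometry reflects
overall bone morphology, not trabecular microarchitecture. Percentiles
use linear interpolation; moments are population moments and kurtosis is
not excess-corrected.

Every matrix builder is validated against an independent brute-force
enumerator (pair counting, run scanning, BFS zone labelling, per-pixel
neighbour loops) with exact integer equality on random irregular ROIs up
to 20×20.

## Resampling

A feature table is a DataFrame with numeric columns and a binary `label`
column; the minority class is the one with fewer rows. All neighbour
searches use Euclidean distance on z-scored features (statistics of the
input table; radiomic features span orders of magnitude) with ties broken
toward the lowest row index, making every technique deterministic given
its seed. Interpolation itself happens in raw feature space, which is
equivalent because standardisation is affine.

Defaults are k = 5 neighbours for SMOTE/ADASYN and k = 3 for ENN, the
conventional library defaults. ADASYN's per-sample quotas are the
normalised majority-neighbour fractions converted to integers by floor
plus largest remainder; when no minority sample has a majority neighbour
the density is degenerate and quotas fall back to uniform. The hybrid
cleaners act *after* SMOTE and remove only members of the **original**
majority class — both because the stated purpose of the cleaning step is
to remove ambiguous or noisy majority samples, and because after
oversampling the class counts are balanced and the table alone can no
longer identify the majority. (Some library implementations clean both
classes by default; this is a documented divergence.) Synthetic rows are
clamped per feature to the [min, max] of the original training table, so
augmented values never leave the observed range. Random undersampling
fully balances the classes by construction.

## Benchmarking

The 70/30 split allocates floor(n_class · 0.7) rows of each class to
training — this floor rule is what reproduces the reference cohort
arithmetic (1531 patients, 185 degraded → 1071 training with 129
degraded, 460 test with 404 healthy and 56 degraded). Cross-validation is
stratified 5-fold, shuffled under the run seed, with identical fold
assignments across classifier families for paired comparability; a fold
missing a class raises `FoldDegeneracy`. Grid search is exhaustive with
ties resolved by enumeration order, and the winner is refit on the full
training table. Features are z-scored inside each fold (fit on the
fold-training part only) — necessary for the SVM, harmless for trees.

Full grids: SVM kernels {linear, poly, rbf} × C ∈ {10⁻⁵..10⁵ in decades}
× gamma ∈ {2⁻²..2⁵ in octaves, auto, scale}; logistic regression
penalties {L1, L2, elastic-net (mixing 0.5)} × the same C range ×
solvers {liblinear, saga, lbfgs} with impossible penalty/solver pairs
skipped rather than errored; XGBoost learning rate {0.01, 0.1, 0.3, 1.0}
× depth {4, 6, 8, 10} × estimators {1, 10, 50, 100, 500}. Reduced grids
(a handful of combinations per family) are used for the test suite and
the shipped experiments so a full 135-cell benchmark completes in
minutes on one CPU. AUC uses predicted probabilities where available and
decision-function scores otherwise; the rank statistic is scale-
invariant. The degraded class is positive everywhere.

## Scaled-down experiment sizes

The qualitative replication experiment (`experiments.
resampling_comparison`) uses five independent cohorts of 240 patients at
120×112 px, extracts only the GLDM and GLRLM families, and searches
reduced LR/SVM grids. 240 patients keeps the feature-to-sample ratio of
the 30-column combined dataset in the same regime as the reference
cohort (a 120-patient pilot penalised the combined set for
dimensionality alone). The non-inferiority margin for the combined-
versus-single comparison is 0.02 mean F-score, fixed a priori. The
dataset-matrix check runs a full 135-cell pipeline on a 60-patient,
20%-degraded cohort — 20% rather than 13% so the training minority count
stays above the SMOTE neighbour count at that size.

## Known limitations

- The generator's class signal lives entirely in texture correlation
  length; first-order features carry almost no class information, unlike
  real cohorts where intensity statistics correlate with bone density.
- Segmentation consumes the generator's annotation conventions (as the
  clinical pipeline consumes the scanner software's); it does not segment
  raw anatomy and has no robustness to missing or corrupted overlays
  beyond raising typed errors.
- Feature values follow the reference radiomics formulary but are not
  certified against any external implementation here; the guarantee is
  exact agreement with the in-repo brute-force definitions.
- The benchmark's absolute numbers on synthetic cohorts depend on the
  chosen effect size and cohort size; only orderings and structural
  counts are treated as findings.
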