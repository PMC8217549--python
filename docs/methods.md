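# Methods

This note documents the models, conventions and design choices behind
`asradiomics`, in the spirit of the methods documentation that accompanies
simulation and statistics packages: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## The prediction problem

Each lesion is one observation. Inputs are a T2WI-like and an ADC-like 3D
volume with an aligned binary mask, six clinical covariates (PSA [ng/mL],
gland volume [mL], PSA density [ng/mL/mL], Likert score {3,4,5}, biopsy
grade group {1,2}, zone {PZ, TZ}) and six acquisition parameters (TE, TR,
flip angle, slice thickness, spacing between slices, pixel spacing). The
target is binary progression status. The pipeline estimates how well
radiomic features, clinical features and their combinations separate the
two arms under leave-one-out cross-validation (LOOCV).

## Feature extraction conventions

All 107 features follow the IBSI-style definitions popularised by the
standard radiomics extraction tooling:

* **Discretisation** is fixed-bin-count over the ROI's own intensity range:
  `level(v) = floor((I(v) - min) / width) + 1`, `width = (max - min) / n_bins`,
  maximum mapped into the top bin. Bin *count* rather than bin *width* is
  the right choice for arbitrary-unit MRI intensities, and it makes every
  discretised feature exactly invariant under a global intensity shift
  (property-tested). No spatial resampling and no intensity resegmentation
  are applied.
* **Texture neighbourhoods live on the voxel lattice**, not in millimetres.
  Since resampling is forbidden, lattice-based offsets are the only
  self-consistent definition on anisotropic grids. Shape features, by
  contrast, use physical spacing throughout.
* **GLCM/GLRLM**: 13 unique direction pairs at Chebyshev distance 1;
  features computed per direction, then averaged without distance
  weighting. GLCMs are symmetrised and normalised per direction. All-zero
  grey-level rows are dropped before feature evaluation (they contribute
  nothing to any sum); the normalising constant `Ng` in Idmn/Idn keeps the
  full matrix dimension.
* **GLSZM** zones are 26-connected components of equal grey level.
  **GLDM** uses the 26-neighbourhood with similarity tolerance alpha = 0;
  a voxel's dependence size counts the voxel itself, so sizes start at 1.
  **NGTDM** uses 26-neighbourhood means over in-mask neighbours.
* **Shape**: voxel volume is `N * prod(spacing)`; mesh volume and surface
  area come from a marching-cubes triangulation (level 0.5) of the
  zero-padded mask after a 0.5-voxel Gaussian pre-smoothing — the raw
  binary staircase overestimates surface area by ~10%, while 0.5 voxel
  keeps the cube's volume within ~3% and brings a digitised sphere's
  sphericity to ~0.95. Axis lengths are `4 * sqrt(eigenvalue)` of the
  physical-coordinate covariance of mask voxel centres; maximum 2D
  diameters are the largest pairwise mesh-vertex distances in each axis
  projection (axis order: row, column, slice).
* **Degenerate inputs**: a constant ROI discretises to a single level and
  is flagged; conventions then fix GLCM Correlation = 1, Imc1 = 0, MCC = 1,
  NGTDM Coarseness = 1e6 when its denominator vanishes, Busyness/Contrast/
  Complexity/Strength = 0 at a single grey level. Skewness/kurtosis of a
  zero-variance ROI and mesh features of sub-4-voxel masks are NaN; NaN is
  *data*, not an error — the robustness screen counts NaN features as
  non-robust and lists them, so they drop out of modelling without
  aborting the pipeline.

## ROI perturbation

"Radius-1 spherical element" is read as the Euclidean ball on the integer
voxel grid — the 7-voxel 6-connected cross — applied in voxel units,
ignoring anisotropic spacing; this matches the common implementations of
morphological mask perturbation. Note that opening with this element is
*not* the identity even on a solid cube: corner and edge voxels are shaved
(the tests pin this down against a direct set-computation oracle). Closing
operates on a zero-padded copy so near-border masks are not truncated; the
generator guarantees a 2-voxel clearance so padding is never load-bearing.

## Calibration

ICC(3,1) is computed from the two-way ANOVA decomposition (rows = lesions,
columns = mask versions): `(MS_R - MS_E) / (MS_R + (k-1) MS_E)` with k = 3.
Negative values are kept (only the > 0.8 decision matters); the degenerate
case MS_R = MS_E = 0 returns 0. The threshold 0.8 is strict (a feature at
exactly 0.8 is non-robust). The operating bin count maximises the combined
T2WI + ADC robust count; ties break toward the smaller count, which is
logged. The implementation is verified to 1e-10 against both an
independently coded ANOVA oracle and `pingouin.intraclass_corr` (ICC(C,1)).

## Acquisition decoupling

Spearman rho with midrank ties and the t-approximation p-value (n-2 df),
each robust feature against each of the six parameters. A feature is
removed iff p < alpha for *any* parameter — the conservative reading of
"decoupling". No multiple-testing correction is applied, matching the
single-threshold design; alpha defaults to 0.001 and is configurable. A
constant parameter (exactly the situation in a single-scanner cohort —
slice thickness and slice spacing in the synthetic metadata are constant by
construction) has no defined rank correlation and is reported as rho = 0,
p = 1, flagged degenerate.

## Feature selection

The six filter methods are named but not specified in the source
literature of this workflow, so the conventional definitions are frozen
here (all "higher is better"; ties break lexicographically):

| method | definition |
|---|---|
| FSCR | `(n1(mu1-mu)^2 + n2(mu2-mu)^2) / (n1 s1^2 + n2 s2^2)` |
| TSCR | Welch t magnitude |
| WLCX | rank-sum distance from its null mean (two-sided) |
| GINI | impurity decrease of the best single split |
| MIM  | MI(feature; label), equal-frequency bins, `ceil(sqrt(n))` |
| MRMR | greedy `MI(f;y) - mean MI(f; selected)` |

The Wilcoxon score is the two-independent-group rank-sum statistic: the
design compares two independent arms, so the "signed-rank" naming that
sometimes accompanies this selector is treated as a misnomer. Top-k caps
are 5 / 10 / 15 for clinical / single-sequence / combined feature sets.

## Predictive modelling

Per held-out lesion: z-scoring, feature selection and hyperparameter tuning
(KNN's k in {1..9}, elastic-net C in {0.01..10} at l1_ratio 0.5, SVM C in
{0.1..10}; inner stratified 3-fold CV) all happen on the training fold
only. Running the selector inside the fold is the default because the
alternative leaks label information; `selection_scope="global"` reproduces
the other reading (selection once on the full cohort) for comparison.
Scores are progressor-class probabilities, except the SVM's decision value
(rank-equivalent, avoiding probability calibration). An elastic net whose
coefficients vanish in every fold is reported as `intercept_only` with no
AUC — the blank-cell convention of the evaluation heatmap.

AUC is the Mann-Whitney pair statistic with ties counted 1/2
(property-tested against brute-force pair counting); the 95% CI is
DeLong's, clipped to [0,1]. The sensitivity/specificity table reports, for
each target, the best achievable partner value over observed-score
thresholds, interpolation-free. With constant scores only the two trivial
operating points exist, so every partner value is 0.

**A caution on null behaviour.** LOOCV AUC under the null is *not*
centred exactly at 0.5: each training fold's class means shift away from
the held-out lesion, making out-of-fold scores mildly anti-correlated with
the truth. At n = 70 the null distribution has mean ≈ 0.45 and SD ≈ 0.15 —
wider and lower than the naive Mann-Whitney null. The null-control tests
assert this actual behaviour (no optimism, centre at or slightly below
0.5) rather than a textbook band.

## The synthetic cohort

The generator emulates the study conditions: 35 progressor and 38 stable
lesions (the published cohort's lesion counts), a single-scanner
acquisition distribution, and planted effects chosen once:

* **Texture**: intratumoural intensity is a Gaussian random field smoothed
  to a correlation length that is log-normal across lesions (median 2 mm,
  log-SD 0.15); progressors get a +1.0 SD shift of the log-correlation
  length. One mechanism shifts many texture features at once without
  hand-tuning 107 of them.
* **Size/shape**: lesions are superellipsoids (exponent 1.8-2.6, random
  axis ratios) with semi-axes 4-9 mm; progressors get a +0.6 SD mean-size
  shift, reflecting the known association between baseline lesion size and
  progression.
* **Clinical**: log-PSA shift +0.6 SD in progressors; gland volume
  group-independent except when the configured PSA-density effect (+0.8 SD
  default) exceeds the PSA effect, in which case the excess is realised as
  a downward gland-volume shift. PSA density = PSA / gland volume is an
  enforced invariant, so the two effects are not independently plantable —
  the chosen construction mirrors the empirical observation that PSA
  density tracks PSA in a homogeneous surveillance cohort. Effect sizes
  correspond to the moderate group differences reported for these markers
  (PSA p ≈ 0.02, PSAD p ≈ 0.003 at n ≈ 71).
* **Both sequences share one mask**; the ADC-like volume is an independent
  field with ADC-scale intensities and the same group-dependent correlation
  length.
* **Grids** are 32 x 32 x 16 voxels at 1 x 1 x 2 mm — large enough for
  300-2000-voxel masks with the 2-voxel border clearance the perturbation
  stage needs, small enough that the full 18-configuration x 73-lesion x
  2-sequence sweep runs in ~3 minutes on one CPU. These are the problem
  sizes used throughout the tests and the acceptance script.

What the phantom does *not* model: MRI physics (coil profiles, bias
fields, Rician noise), anatomy, multi-scanner heterogeneity, or
reader-specific segmentation styles beyond the two morphological
operators. Two consequences matter for interpreting results. First, the
smooth phantoms are highly perturbation-robust: typically all 107 features
pass ICC > 0.8 at every bin count, so on synthetic data the bin selection
degenerates to the tie rule (smallest bin count). The discriminating
regime of the ICC screen — some features robust, some not — is therefore
exercised by direct variance-ratio simulations (rater noise at 5% vs 200%
of subject SD, analytic ICC = 1/(1+r^2)), not by the phantom. Second,
passing tests demonstrate internal statistical correctness and
planted-effect recovery, not clinical performance; the published
real-data AUCs depend on the unavailable patient cohort and are only
mirrored directionally (clinical-only < combined) by the planted synergy.

## Known limitations

* Feature values are *conventions-compatible* with the reference
  extraction tooling, not bit-identical to any specific release of it;
  where that tooling's behaviour and the IBSI text diverge, the choice
  made here is documented above.
* The LOOCV grid at full size (7 x 6 x 6 cells, 73 folds each, inner CV in
  three classifiers) is expensive; the default orchestration and the
  acceptance script use the 2-selector x 2-classifier reduction, which is
  sufficient for every question the synthetic experiments ask.
* Lesions are treated as independent units in LOOCV; `patient_id` is
  emitted for grouped folds but grouping is not applied by default (the
  source cohort had 73 lesions in 71 patients, an ambiguity the original
  design leaves unresolved).
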