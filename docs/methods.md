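# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the tests do and do not establish.

## Deformation-based morphometry

A displacement field u(x), in millimetres on a regular grid, is taken to
map template coordinates to subject coordinates. The DBM value at a voxel
is `det(I + ∂u/∂x)`: > 1 means the subject is locally larger than the
template. This direction convention matters — some registration packages
store the inverse warp — and is stated here once because it cannot be
recovered from the field itself. The gradient uses second-order central
differences on interior voxels and one-sided differences at the boundary,
scaled by the voxel spacing; the 3×3 determinant is expanded in cofactors
(exact). The map therefore reproduces the analytic value s³ of a uniform
scaling by s on all interior voxels to machine precision.

Whether an upstream registration's affine component should contribute to
the determinant is a pipeline-level decision; this package computes the
determinant of the *supplied* total field and leaves affine removal to
the caller.

Smoothing is a separable Gaussian parameterized by FWHM
(σ = FWHM / (2√(2 ln 2)) per axis, converted to voxels by the spacing).
The kernel is truncated at 4σ and renormalized; at the volume boundary
the truncated weights are renormalized again, so constants are preserved
everywhere and edges are not dimmed by zero-padding. Consequence: total
intensity is conserved only for mass whose smoothed support stays clear
of the boundary zone (within one truncation radius of a face); inside
that zone the renormalization trades mass conservation for level
preservation. No image-quality gate is built in — synthetic inputs are
clean — but the selection stage accepts an external include list.

## Synthetic cohorts

The generator emulates the structure of a multi-site de novo PD imaging
study with five years of follow-up; defaults are the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_pd`, `n_hc` | 314, 143 | patients / controls |
| `biotype_fractions` | 114/314, 200/314 | planted biotype split |
| `grid_shape`, `voxel_spacing_mm` | 24³, 8 mm | downsampled whole-brain grid |
| `n_sites` | 4 | sites, round-robin with seeded permutation |
| `effect_size` | 0.8 | planted mask shift in per-voxel noise SDs |
| `severity_sd` | 0.25 | within-patient spread along the planted axis |
| `site_effect_sd` | 0.10 | per-site additive offset, drawn once per site |
| `age_effect`, `sex_effect` | 0.05 | confound effects on voxel values |
| `score_noise_sd` | 1.0 | score noise, in units of each score's SD |
| `visit_months` | 0,3,…,12,18,…,60 | quarterly year 1, then 6-monthly |
| `random_intercept_sd`, `random_slope_sd`, `residual_sd` | 2.0, 0.1, 1.0 | longitudinal variance components |

Biotype allocation uses largest-remainder rounding of the fractions (so
counts are exact) followed by a seeded permutation (so assignment is
random). The planted "subcortical" mask is the central third of each axis
(8³ = 512 voxels at default size), strictly interior. Patients in biotype
1 receive a −0.8 SD shift inside the mask, biotype 2 +0.8 SD, controls
none; each patient additionally carries a persistent severity scalar
(SD 0.25) along the same axis. Voxel noise is iid unit-variance Gaussian.
Baseline clinical scores are linear in the patient's realized mean mask
signal — negative coefficients, so smaller subcortical volume means worse
scores — with per-score means and SDs at published de novo PD values
(e.g. UPDRS-III 20.7 ± 8.7) and a weaker link for tremor. Longitudinal
outcomes follow subject-level random intercepts and slopes around
biotype-specific mean slopes; tremor's planted slopes are equal across
biotypes, every other scale declines faster in biotype 1.

**Grid emulation.** The 24³ grid at 8 mm spacing spans ≈ 19 cm — a
whole brain at coarse resolution — so the conventional 8-mm FWHM kernel
is a mild σ ≈ 0.42-voxel filter, as it is (relative to the field of
view) on a full-resolution grid. Emulating the grid at high resolution
instead (e.g. 2-mm voxels spanning only 5 cm) makes the same kernel span
the whole volume: iid voxel noise is annihilated, a single principal
component carries > 90% of the variance, and correlation distance between
subjects degenerates. The spacing default encodes this choice.

What the generator does *not* emulate: spatially structured anatomical
covariance, registration error, scanner-specific noise spectra, ordinal
score floors/ceilings, or informative dropout. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
generative model, not performance on real MRI; the near-perfect ARI, κ
and SVM metrics on synthetic cohorts are upper bounds that real data will
not reach.

## Feature selection

Confound residualization is ordinary least squares per voxel on
intercept + age + education (continuous) + sex, race, site (dummy-coded).
The model is fitted within the patients — selection happens within the
PD group — and the fitted coefficients (with frozen category levels) are
applied to controls when the groups are later compared on one scale.
Voxel values are residualized; the clinical scores are not — rank
correlation already absorbs monotone score distortions, which covers the
main effect of residualizing a score. Spearman ρ is the Pearson
correlation of mid-ranks (average ranks on ties); two-sided p-values use
the t approximation t = ρ√((n−2)/(1−ρ²)), adequate at the n ≈ 300 scale
this pipeline targets and tested against the exact implementation in
scipy. Selection is deliberately *uncorrected* at α = 0.01 per score —
the point is sensitivity, with dimensionality subsequently reduced by
PCA — and per-score complete cases are used when scores are missing
(< 10 complete cases is refused).

## Biotyping

PCA is computed on centred, unstandardized columns (the features share a
scale by construction; a caller can standardize first if not). The
retained dimension is the smallest k with cumulative explained variance
≥ the target (0.90), with a floor of 2 components because the next step
correlates subject rows. Participant dissimilarity is 1 − Pearson between
component-score rows; Ward linkage is applied to these dissimilarities
via the Lance–Williams update. Ward formally assumes squared Euclidean
input, so this is a heuristic — used knowingly, because it is the
field's convention for this analysis; `ward_cluster` accepts any
precomputed dissimilarity, so a Euclidean sensitivity analysis is one
call away. Merge ties resolve to the lowest-index pair (scipy's
deterministic ordering). The cluster number maximizes Calinski–Harabasz
over k = 2…10, evaluated with Euclidean geometry in component space (CH
is variance-based; there is no canonical correlation-distance variant).
k-means (best of 50 seeded Lloyd runs) provides a cross-method check;
Cohen's κ is computed after exhaustively aligning the label permutation
(k ≤ 6) that maximizes raw agreement — the alignment convention is
declared here because κ is meaningless for unaligned cluster labels.
For k = 2 the final labels are oriented so biotype 1 is the cluster with
the lower mean selected-feature value, i.e. the atrophy group.

## Validation

Voxelwise contrasts are pooled-variance two-sample t tests on
confound-residualized values, df reduced by the number of non-intercept
design columns; zero-variance voxels are NaN and excluded from the FDR
family. The Benjamini–Hochberg step-up controls FDR across in-mask
voxels; the conventional display threshold q = 0.005 is interpreted as
the BH level (equivalently the adjusted-p cutoff — at BH these coincide).
The classifier is an RBF-kernel SVM (C = 1, γ = "scale" = 1/(d·var))
inside stratified 10-fold CV, with feature standardization fitted on each
training split only; metrics come from pooled out-of-fold predictions and
the AUC from pooled decision values. The positive class is biotype 1 (the
minority). Note a deliberate replication choice: voxel selection runs on
the full sample *before* cross-validation, as the reference analysis did,
which leaks selection information into the folds; re-selecting within
folds is the statistically clean variant and the package exposes the
selected-feature matrix so callers can do either.

## Progression

Each outcome is fitted by REML with fixed effects for biotype, time,
their interaction, age, sex, race and site (site as fixed dummies, not
random intercepts), and correlated subject random intercepts and slopes.
Internally time is rescaled to years — with five years of follow-up on a
monthly scale the slope variance is ~10⁴ smaller than the intercept
variance and the optimizer stalls on the raw parameterization — and all
reported coefficients are converted back to per-month units. Inference is
Wald z on fixed effects (no degrees-of-freedom correction; a
Satterthwaite hook is left open). A singular random-effect covariance
triggers an automatic refit with independent intercept and slope
components, noted on the result; non-convergence is flagged, never
silent. If the fixed-effects OLS residual variance is numerically zero
(relative 1e-16) the variance components are unidentified and the OLS
solution — exact in that degenerate case — is returned, flagged. The
summary reports both the slope contrast β_int and the per-biotype
marginal slopes, BH-adjusted across the outcome family at q = 0.05.
Baseline level differences enter through the biotype main effect; no
baseline subtraction. Per-visit uncorrected group comparisons can be
produced with the validation module's t-test if a visit-by-visit display
is wanted.

## Pipeline

A single master seed spawns one child seed per stage
(`numpy.random.SeedSequence`), each recorded in the manifest, so one
integer reproduces a run. All tables are CSV, volumes NIfTI-1, voxel
indexing 0-based half-open throughout. The manifest stores SHA-256 hashes
of every artifact; `verify_manifest` re-hashes and reports tampering.

## Problem sizes used by the tests

The suite runs desk-scale versions of each experiment, chosen as the
smallest sizes at which the checked properties are stable: selection
calibration pools 20 seeded null cohorts of 300 patients × 2,000 voxels
per score and compares the pooled rate to the exact binomial 99% interval;
biotype recovery uses 20 cohorts of 200 patients at the default 0.8 SD
effect; mixed-model CI coverage uses 200 replicates of 40 patients per
biotype × 13 visits (coverage is a property of the estimator, not of the
sample size, so the smaller cohorts are a fair probe); the end-to-end run
uses 120 patients + 60 controls on the 24³ grid.

## Known limitations

- Ward-on-correlation-distance has no variance-minimization guarantee;
  CH in Euclidean component space mixes geometries (both deliberate
  replication choices, see above).
- Wald inference in the mixed model is mildly anticonservative in small
  samples; the coverage test quantifies this at the sizes used.
- The classifier replicates whole-sample feature selection (optimistic);
  nested selection is the honest variant for performance claims.
- No informative-dropout modelling; dropout in the generator is missing
  completely at random.
- Soft/probabilistic biotype membership, consensus clustering and
  bootstrap stability curves are out of scope.
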