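# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Seed masks from a probabilistic atlas

A probabilistic atlas gives each voxel a probability of belonging to each
of six amygdala subregions (left/right CMA, BLA, SFA). The label volume
assigns a voxel to the arg-max structure iff that probability is
**strictly greater than 0.10** and strictly beats every competitor, so the
per-structure masks are pairwise disjoint. Exact ties are resolved in
favor of the structure declared earliest, with a warning; this keeps the
label volume deterministic under reordering of the probability volumes
everywhere except at ties. Probabilities supplied on a 0–100 scale are
rescaled to [0, 1] (logged) whenever any value exceeds 1. The package is
space-agnostic: geometry (voxel size, affine) is carried as metadata, and
registration between native and template space is out of scope. Voxel ↔
feature indexing is row-major and 0-based throughout.

The 10% cutoff is applied to the winning probability itself, not to its
margin over competitors; the arg-max win is additionally required.

## Motion QC

Framewise displacement is the Power form: the sum of absolute backward
differences of the three translations (mm) plus the three rotations
converted to arc length on a 50 mm sphere. Exclusion uses strict
inequalities: mean FD > 0.3 mm, any |translation| > 3 mm, or any
|rotation| > 3° (parameters are stored in radians and converted for the
comparison). A subject with mean FD exactly 0.3 mm is kept.

## Band-pass filter

Series are linearly detrended, then filtered with an ideal (hard)
frequency mask in the DFT domain keeping 0.01 ≤ f ≤ 0.08 Hz. The hard
mask was chosen over an IIR/FIR design because it is exactly testable
against an explicit Fourier oracle and has no transient or phase
artifacts; its ringing is irrelevant to the correlation statistics
computed downstream. Constant series return as zeros with a warning
rather than an error so degenerate voxels flow through the pipeline.

## Connectivity maps

Each seed's mean time series is correlated (Pearson) with every
grey-matter voxel series; r is clipped to |r| ≤ 1 − 1e-7 and mapped to
Fisher z = atanh(r), which keeps z finite for voxels identical to the
seed mean. Zero-variance voxels get r = 0; a zero-variance seed mean is
an error reported per subject. No global-signal or tissue regression is
applied, and spatial smoothing is treated as upstream preprocessing.

## Site harmonization (ComBat)

The location/scale empirical-Bayes model: after fitting a standardization
model by least squares (site intercepts + preserved covariates, pooled
residual variance with a 1/n denominator), each site's per-voxel mean
(γ) and scale (δ², estimated with n−1) are shrunk toward site-level
priors — normal for location, inverse-gamma for scale, hyperparameters by
method of moments — via iterated conditional posterior means (tolerance
1e-4, max 100 iterations). Adjusted data are re-centered/rescaled by the
shrunk effects and the preserved-covariate structure restored. These
numerics deliberately match the widely used reference implementation,
and the test suite verifies agreement with it on a small stack.

Consequences worth knowing:

* **Not exactly idempotent.** Because the pooled variance uses 1/n while
  site scales use n−1, harmonizing already-harmonized data rescales
  deviations by √(n/(n−K)) (≈1–2% at typical cohort sizes). The tests
  assert this bound and that a second pass keeps the site ANOVA null;
  exact idempotence would require departing from the reference numerics.
* **Single site is the identity.** With one site there is nothing to
  harmonize; the fitted model is a flagged no-op.
* **Zero-variance voxels** (within any site) pass through unharmonized
  and are flagged.
* The group indicator is preserved by default (configurable) so the
  between-group signal is not absorbed into the site correction. Which
  covariates to preserve is a genuinely open design point; group-only is
  the conservative default for a two-group contrast.

Validation uses the per-voxel one-way site ANOVA before and after
harmonization, summarized as the fraction of voxels with p < 0.05.

## Group statistics

Within-group maps are one-sample t tests of Fisher-z values against zero
with voxel-level **Bonferroni** FWE (α = 0.05) plus a cluster-extent
filter. Bonferroni replaces random-field-theory FWE: at desk scale it is
conservative and exactly testable against the α/m rule; RFT is a
non-goal. The union of the two group masks defines the search space for
the between-group GLM (intercept + group + age, sex (0/1),
education-in-years), whose group-coefficient t is thresholded by
Benjamini–Hochberg FDR at q = 0.05 followed by the cluster filter
(≥ 10 voxels; connectivity 18 by default, configurable to 6 or 26). The
cluster rule is applied after voxel thresholding. Zero-variance voxels
report t = 0, p = 1. Two-tailed tests throughout; the sign of the group
contrast is recorded separately as the direction map. A seed with an
empty difference mask is a valid outcome and is excluded from PLS.

## Behavioral PLS correlation

With z-scored X (N × M) and Y (N × B), the SVD of R = XᵀY yields voxel
saliences V (M × L), behavior saliences U (B × L) and singular values S,
with L = min(M, B). (Descriptions of this analysis sometimes state that
the number of LVs equals B; that only holds when B ≤ min(M, N−1), so the
rank bound is used here.) Scores are L_X = XV and L_Y = YU; explained
covariance is s²_l / Σ s². Sign indeterminacy is fixed by orienting each
LV so its largest-magnitude behavior weight is positive.

Inference:

* **Permutation test** — rows of X are permuted with Y fixed (row
  permutation preserves column means/sds, so no re-z-scoring); null
  singular values are compared rank-for-rank without Procrustes rotation
  of the permuted subspaces (the rotation variant used by some toolboxes
  is intentionally not implemented); p = (1 + #{s_perm ≥ s_obs})/(1 +
  n_perm), never exactly zero.
* **Bootstrap** — subjects are resampled with replacement jointly in X
  and Y, each replicate re-z-scored (necessary, since resampling changes
  column statistics) and refit; replicate LVs are sign-aligned to the
  observed V by dot product. BSR = observed weight / bootstrap SE
  (n−1). Replicates that collapse a column to a constant are redrawn and
  counted; more than 20% redraws aborts with a diagnostic. |BSR| ≥ 3.3
  (boundary inclusive) marks stable voxels; 2·(1−Φ(3.3)) ≈ 0.00097
  justifies the "p < 0.001" reading.
* **Behavior loadings** — observed corr(Y_b, L_X) with percentile 2.5/97.5
  bootstrap CIs; significant iff the CI excludes zero.

Two analysis modes mirror common practice: the plain mode fits PLS on the
feature set as given; the confound-controlled mode residualizes a
confound matrix (OLS, with intercept) out of **both** X and Y before
z-scoring. A combined model concatenates the per-seed difference-mask
matrices feature-wise, recording each feature's seed of origin.

One subtlety for recovery studies: z-scoring equalizes column scales, so
a planted salience is recovered up to the per-column standardization. The
generators therefore plant saliences with equal-magnitude nonzero
entries, for which the standardized direction coincides with the planted
one.

## Synthetic data generator

`simulate_dataset` builds the whole study at desk scale. Defaults are the
study conditions: grid 16³ (3 mm voxels as metadata), 2 sites × 2 groups
× 20 subjects, TR 2 s, 160 frames, six Gaussian-profile seed structures,
two 3×3×2 target blocks per seed, r_HC = 0.5 seed–target correlation,
patient reduction Δ = 0.5 Fisher-z units planted in four seeds (left
CMA/BLA/SFA + right BLA), 10% high-motion subjects, and a rank-1 latent
link: each patient's severity scales both their connectivity reduction
(heterogeneity 0.4) and, through the true behavior salience u* over a
10-item non-motor-symptom inventory (UPSIT, MoCA, RBD-SQ, ESS, QUIP,
GDS-15, STAI state/trait, and two UPDRS-I items — labels only; the
simulated marginals are schematic), their symptom scores. Site effects
enter twice: a site-shared signal added to every grey-matter voxel
(additive map shift, amplitude 0.2) and a multiplicative factor (1.1) on
the target z. Time series are Gaussian with no hemodynamic model or
autocorrelation: every downstream statistic is correlation-based, so this
preserves the quantities under test; consequently passing tests say
nothing about hemodynamic confounds, spatial autocorrelation, or
registration error in real data. Demographics are generated independent
of group (a matched design). Everything is reproducible bit-for-bit from
one master seed.

Matrix-level helpers plant the same structures directly in feature
space: `simulate_pls_matrices` (rank-1 link with `link_strength` the
variance fraction the latent explains per block; the default true voxel
salience is 20%-sparse with equal weights) and `simulate_site_stack`
(additive/multiplicative site effects with a uniform patient reduction;
between-subject noise SD 0.3, a realistic scale for Fisher-z maps).

## Problem sizes used in tests and the acceptance script

Calibration and recovery studies run at sizes chosen to make Monte-Carlo
error small relative to the asserted margins while keeping the default
run fast: permutation calibration at 500 replicate null cohorts (N = 40,
M = 50, B = 5, 200 permutations); link recovery at 50 cohorts (N = 80,
M = 200, B = 10, 200 bootstraps); the end-to-end study at 20 simulated
cohorts of 40 subjects (10 per group per site), 120 frames, 100
permutations. The full-scale defaults (1000 permutations/bootstraps)
remain available through the API and CLI.

## Known limitations

* Harmonization is linear in location/scale; nonlinear or
  interaction-aware site corrections are out of scope.
* FWE control is Bonferroni, not random-field theory or TFCE.
* The generator's BOLD model is white Gaussian (optional AR structure is
  not enabled by default); slice timing, realignment, normalization and
  smoothing are upstream concerns not modeled here.
* PLS here is the correlation (SVD of cross-covariance) variant —
  predictive PLS regression, sparse PLS and CCA are non-goals.
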