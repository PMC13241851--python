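# Methods

This note documents the models implemented by `neuroenergetics`, the
parameters that matter, the synthetic data the tests rely on, and the
numerical and design choices that were genuinely open.

## Energetics metrics

For each subject, regional CMRglu and CBF vectors are z-scored across
regions (sample SD, denominator N−1) and rotated:

    rEP = (z(CBF) + z(CMRglu)) / √2
    rAG = (z(CMRglu) − z(CBF)) / √2

The rotation is orthonormal, so per region-pair Euclidean norm is preserved,
and because both z inputs have unit variance, rEP and rAG are exactly
uncorrelated across regions within a subject.  The choice of SD denominator
is irrelevant to any correlation-based downstream quantity; N−1 is fixed
here for reproducibility.  Missing regional values are rejected rather than
imputed — the intended inputs have complete regional coverage, and silent
imputation would distort the z-scores of every other region.

rAG is a *proxy* for aerobic glycolysis: it reads relative CMRglu in excess
of relative CBF as glycolytic preference, which identifies aerobic
glycolysis only under spatially uniform oxygen extraction fraction.  The
package does not test that assumption (no CMRO₂/OEF computation).

## Kinetic quantification

* **Patlak.** Ki is the OLS slope of C_tissue(t)/C_p(t) against
  ∫₀ᵗC_p dτ / C_p(t) over frames with mid-time ≥ t*, with the cumulative
  integral computed by the trapezoid rule on the plasma grid and linear
  interpolation to frame times.  Default t* = 20 min: for grey/white-matter-
  like FDG kinetics (k₂+k₃ ≳ 0.15 min⁻¹) the reversible compartment has
  equilibrated enough that Ki is recovered within 2% of K₁k₃/(k₂+k₃) on
  noiseless simulations; slower kinetics need a later t*, which is why the
  parameter is exposed.
* **CMRglu** = Ki·Cglu/LC with the lumped constant LC = 0.65 by default.
* **IDIF.** The image-derived input function uses a deliberately simplified
  rule: candidate voxels above a fraction of the temporal-MIP maximum, then
  greedy removal of the voxel whose exclusion most reduces the squared
  mismatch with three late venous samples, never dropping below
  `min_voxels`.  This reproduces the *anchoring* idea (late venous samples,
  where arterial–venous differences are minimal, constrain the curve tail)
  but is not a reimplementation of any published spatiotemporal selection;
  treat absolute IDIF scaling with caution.
* **Putamen subdivision.** Anterior/middle/posterior thirds from the
  anterior–posterior voxel indices.  One-dimensional k-means is solved
  *exactly* (the optimal partition in 1-D is contiguous in the sorted
  values; boundaries are found by direct search with prefix-sum segment
  costs).  An iterative Lloyd scheme with fixed quantile initialization was
  considered and rejected: it can land in local optima on ordinary index
  distributions, whereas the exact search is deterministic,
  initialization-free, and always the minimal within-cluster-SS partition.
  The AP axis and its direction are explicit metadata (`ap_axis`,
  `anterior_low`), never guessed from headers.

## Age-related pattern derivation (SSM-PCA)

Residual profile: R = X − row means − column means + grand mean.  rEP/rAG
enter SSM directly without a log transform (they are signed, unit-free
z-scale quantities; a log option exists for raw positive CMRglu inputs).
PCA is the SVD of R; weights are unit-norm right singular vectors (sign:
largest-|weight| region positive), VAF_k = 100·σ_k²/Σσ².

Component filter: VAF > 5% and younger/older score separation p < 0.2 by
the equal-variance two-sample t-test (Welch was the alternative; with
near-balanced groups of ~11–13 the two are nearly identical, and the
equal-variance form is fixed for determinism).

Stepwise recombination: forward selection over filtered components (VAF
order), adding the component whose score-predictor most lowers AIC of the
logistic model for older-group membership, stopping when no addition
lowers AIC.  The logistic fit is Newton–Raphson with a tiny L2 ridge
(1e−8) and an iteration cap of 25 so perfect separation — likely at n = 24
— yields large-but-finite coefficients; AIC uses the *unpenalized*
log-likelihood.  Note that AIC admits a null predictor with probability
≈ P(χ²₁ > 2) ≈ 0.16, so occasional co-selection of a noise component
alongside a true one is expected behaviour, not a defect.

Cross-validation: 500 iterations of 5-fold partitions, stratified by age
group so every training set contains both groups (required by the t-test
filter).  Candidate components are re-derived within each training fold —
the stricter reading of fold-wise derivation.  Fold patterns are
sign-aligned to the first retained pattern; final weights are the mean
across retained fold-patterns, renormalized to unit norm (the per-region SD
is scaled by the same factor so weight and spread stay commensurate).
Final scores project the full-cohort residual profile onto the final
weights, oriented so scores increase with age.

**Known limitation — in-sample expression p-values.** The final pattern is
selected to separate age groups and then scored on the same subjects, so
the score–age r² and its p-value are *descriptive*, not calibrated
inferential quantities: on null cohorts (no planted pattern) about 95% of
runs reach nominal p < 0.05.  This was verified to be selection bias rather
than leakage — projecting the same derived weights onto an independent null
cohort gives uniform p-values.  For calibrated inference about the
*existence* of an age effect, use the PLSC permutation test, which is
properly calibrated (type-I ≈ 5–7% at nominal 5% in 100–200-cohort runs);
the CV weight SDs quantify topographic stability, not significance.

Display rule: weights are standardized to SD 1 across regions and a region
is displayed when |w| − σ(w) > 1 (threshold configurable); a bilateral
partner is shown when either side passes, given a laterality map.

## PLSC

X (subjects × regions) and Y (subjects × clinical) are column-standardized;
C = YᵀX/(n−1) is the clinical-by-region correlation matrix; SVD C = UΣVᵀ
gives paired saliences and subject scores XV, YU.  Sex is coded ±0.5 before
standardization; age standardized — conventional PLSC coding.  Inference is
the standard substitute (the exact original cross-validation variant being
unspecified): row-permutation of Y for per-LV p-values
(p = (1+#{σ_perm ≥ σ_obs})/(n_perm+1), defaults 1000 permutations) and
subject bootstrap (default 500) with orthogonal Procrustes alignment for
salience stability ratios.  Outputs are labelled accordingly.

## Topographic profile rating

rSRP = log(rCMRglu) − rGMR − rGMP with the natural log (the base only
rescales all scores by a common factor).  Because rGMR (the subject's mean
log rate) is subtracted, scores are exactly invariant to global
multiplicative scaling of a subject's CMRglu.  By default the rDRP weights
are additionally mean-centered across regions before projection, making
scores invariant to any region-constant residual offset; the uncentered
behaviour is available via `center_rdrp=False` since the original weighting
convention is not fixed.  Scores are deliberately unstandardized — only
their covariation with other expression measures is meaningful.  The
disease-comparison family (2 metrics × 3 patterns) uses Bonferroni m = 6.

## Synthetic cohort generator

Log-additive model per subject i, region r, modality m:

    log v[i,m,r] = g_i + b[m,r] + e_i·P[m,r] + ε,   ε ~ N(0, noise_sd²)

with g_i ~ N(0, global_scale_sd²) a per-subject global factor, b a
region-baseline profile per modality, P a unit-norm planted pattern and
e_i = age_slope·(age_i − mean age) + group_effect·[age_i > cutoff] its
expression.  Concordant mode plants +P in both modalities (an rEP effect);
discordant plants +P in CMRglu and −P in CBF (an rAG effect).  Ages are
uniform over 35–80 y; sex alternates (balanced).  All randomness flows from
one integer seed through named `SeedSequence` streams in a fixed order
(baselines, pattern, ages, global factors, CMRglu noise, CBF noise), so
cohorts are bit-reproducible.

Defaults and why:

| parameter        | default | rationale |
|------------------|---------|-----------|
| n_subjects       | 24      | study-scale cohort size |
| n_regions        | 97      | study-scale ROI count |
| age_range        | 35–80 y | broad aging window |
| noise_sd         | 0.3     | log-scale regional noise at which recovery is tested |
| global_scale_sd  | 0.1     | ~10% inter-subject global variation |
| baseline spread  | 0.25    | ~25% regional spread around CMRglu ≈ 30, CBF ≈ 45 |
| age_slope        | 0.15/y  | see below |
| group_effect     | 0       | the age slope alone separates the groups |

The expression amplitude (age_slope) was set by a forward design
calculation: the planted log-scale pattern survives exp + per-subject
z-scoring only up to a cosine ceiling of ≈ 0.98 (baseline-profile
modulation), and at noise_sd = 0.3 an amplitude of 0.15/y leaves the
recovered-vs-planted cosine at 0.93–0.97 across seeds and modes, with
wrong-metric cosines ≤ 0.16 and group separation d ≈ 3–5.  This is a
*strong* age effect — deliberately stronger than typical empirical
score–age fits — so that recovery failures signal implementation defects
rather than SNR bad luck.  What passing tests show is therefore that the
machinery recovers a recoverable topography and rejects the orthogonal
one; they do not show field-realistic effect-size sensitivity, nor do the
synthetic cohorts contain spatially correlated noise, hemispheric symmetry,
or region-size-dependent variance, all present in real data.

The dynamic-data generator integrates the irreversible two-tissue
compartment model (dC₁/dt = K₁C_p − (k₂+k₃)C₁, dC₂/dt = k₃C₁) on a fine
grid with an exact exponential-kernel update, driven by a gamma-variate
plasma bolus (peak ≈ 1 min) plus a slow washout tail (τ = 80 min) that
keeps late plasma activity realistically non-zero for Patlak and venous
anchoring.  Any tabulated input curve is accepted.

## Numerical choices and degenerate inputs

* Zero-variance regional vectors, non-finite values, non-positive CMRglu
  for TPR, constant clinical columns, empty age groups, and label/parametric
  grid mismatches all raise immediately with specific messages.
* Patlak r² is reported as 1 for an exactly-fit constant ratio (pure
  vascular signal) instead of the 0/0 ambiguity.
* PCA rejects inputs that are not double-centered instead of silently
  centering them.
* Cross-validation raises `PatternDerivationError` (with fold diagnostics)
  if every fold yields an empty model.
* TSVs are written with `%.17g` and read with round-trip float parsing, so
  write∘read is bit-exact and resumed pipelines reproduce downstream
  artifacts byte-for-byte.
* Pipeline sub-seeds derive from the config seed via
  `SeedSequence(seed, spawn_key=(stage,))` in a documented stage order, so
  stages rerun in isolation reproduce the full run.

## Problem sizes used by the test suite and acceptance script

Unit tests run on compact cohorts (≈ 12–16 subjects, 15–30 regions) with
reduced CV iteration counts; recovery and concordance checks run at full
study scale (24 × 97, 500 × 5-fold CV).  Null-calibration runs use 100–200
null cohorts with 20 CV iterations per cohort — the calibration behaviour
of the in-sample age fit does not depend on the iteration count, which only
smooths the fold-mean weights.  The acceptance script reports the problem
size next to every quantity.
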