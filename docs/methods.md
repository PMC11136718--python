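# Methods

This note documents the generative model behind the synthetic cohort, the
analysis conventions, and the design choices made where the design was
genuinely open. Units: MD is always in 10⁻³ mm²/s; volumes in mm³ unless a
field name says mL; all Z-scores are referenced to the healthy-control
(HC) sample only.

## The synthetic study

### Atlas

The toy parcellation tiles a 24×24×18 voxel grid (1 mm isotropic) with
3³-voxel cubes and labels the first 212 of them as regions; the remainder
is background. Regions are assigned round-robin to the seven networks
(SMN, VAN, DAN, FPN, DMN, visual, limbic — so each network holds 30–31
regions) and alternately to the two hemispheres. Geometry is deliberately
meaningless: the downstream statistics consume only label bookkeeping
(region → network, voxel counts, volumes), so axis-aligned blocks exercise
every code path that folded cortical anatomy would. One consequence worth
knowing: regions with consecutive labels are spatial neighbours along z,
so a lesion sphere seeded in one network can spill into regions of the
"next" network in round-robin order. This blurs, but does not reorder,
the network lesion-rate profile.

### Subject images

Per subject, each region's FA and MD are

    value(region) = healthy baseline(region)
                  + phenotype/network MD shift
                  + subject-level regional effect ~ N(0, σ_between)
                  + voxelwise noise ~ N(0, σ_voxel)

* Healthy baselines are drawn once from a fixed internal seed (decoupled
  from the sampling seed, so the "anatomy" is stable across study draws):
  MD ≈ N(1.02, 0.015) clipped to [0.94, 1.10], FA ≈ N(0.18, 0.008). The
  between-subject SDs are σ_between = 0.04 (MD) and 0.01 (FA), matching
  the dispersion of regional cortical values in controls; voxel noise is
  small (0.01 / 0.005) so regional means are dominated by the
  between-subject term.
* Non-lesional MD shifts by phenotype: CP +0.03 in every network,
  mildly CI +0.05 in every network, CI +0.03 except +0.07 in DMN, FPN and
  SMN. The CI-specific excess over CP (+0.04) is therefore *confined* to
  those three networks — the spatial pattern the recovery suites test.
* Partial-volume map: 1.0 at region-core voxels (all 6-neighbours share
  the label), 0.7 at boundary voxels, 0 outside cortex. This exercises
  the weighting without surface models.

### Lesions

An MS subject is lesion-free with phenotype-specific probability
(CP 15/95, mildly CI 2/37, CI 5/44), giving an expected overall CL
prevalence of 154/176 = 87.5%. Otherwise per-network lesion counts are
Poisson with rates (VAN 2.0, limbic 1.2, DMN 1.1, SMN 0.8, DAN 0.7,
FPN 0.7, visual 0.3) scaled by phenotype (CP ×1, mildly CI ×2, CI ×2.5);
if every count comes up zero a single lesion is forced so presence and
counts stay consistent. Each lesion is a sphere of radius 1–3 voxels
centred on a uniformly drawn cortex voxel of its network, clipped to
cortex, so every mask voxel lies inside an atlas region. Regions touched
by ≥ 1 lesion voxel are *lesional* and additionally receive +0.01 FA and
+0.03 MD over their whole extent, making lesional cortex measurably
"hotter" than non-lesional cortex within the same subject.

The VAN rate is set clearly highest so that the VAN dominates the median
CL volume fraction per network; because the toy networks have near-equal
volumes, fraction ordering follows rate ordering directly, which is not
true of real anatomies.

### Cognition, covariates, clinical scores

Domain scores are drawn per phenotype around fixed (mean, SD) pairs per
domain — e.g. information-processing speed: CP −0.67 (1.06),
mildly CI −2.03 (0.96), CI −2.81 (1.29); HC means are 0 by construction.
A covariate adjustment (−0.02 per year of age, +0.25 for female, +0.30
for high education) is *centred within phenotype*, so older/male/
low-education subjects do worse without moving the group means. MS
domain scores are missing completely at random at 2% per domain, never
leaving fewer than two scorable domains. Age, sex and education are drawn
from phenotype-specific distributions (e.g. HC age N(50.8, 7.0), CI age
N(55.5, 9.6)); EDSS is a rounded, clipped normal per phenotype and the
MS subtype (RR/SP/PP) categorical per phenotype.

### What the generator does not emulate

Cortical folding and surface geometry, scanner noise structure and
artifacts, spatial autocorrelation of diffusivity beyond region blocks,
lesion subtypes (I–IV), registration error, and any longitudinal
structure. Passing tests therefore demonstrate the *analysis chain* is
correct and well calibrated under the assumed generative structure; they
say nothing about segmentation or preprocessing quality on real images.

## Analysis conventions

* **Lesional threshold**: a region is lesional with ≥ 1 lesion voxel; no
  minimum-overlap fraction. Lesion voxels outside every region are
  tallied and reported (`out_of_atlas_voxels`), never silently dropped.
* **Lesion counting**: 26-connected components of the whole-subject mask
  (configurable to 6/18); per-region tallies are voxel counts, so both
  "components in mask" and "regional load" views are available.
* **Subject summaries** average regions un-weighted (each region one
  unit) within tissue class (all / non-lesional / lesional) and
  network × tissue cells; empty cells (e.g. lesional cortex in a
  lesion-free subject) are missing, never zero.
* **Z-scoring** uses the HC reference exclusively. Regions with zero HC
  variance are flagged unusable and their Z-scores are missing. Controls
  Z-scored against their own reference have per-region mean exactly 0
  and SD 1 (n−1 convention).
* **Welch vs pooled t** is chosen per comparison by a Levene variance
  screen (p < 0.05 → Welch), reproducing the mixture of fractional and
  integer degrees of freedom such cohort tables show.
* **χ²** is Pearson's statistic without continuity correction. U and H
  use midranks with tie correction; U's p is the normal approximation
  without continuity correction.
* **Normality screen**: Lilliefors-corrected Kolmogorov–Smirnov (the
  reference normal has estimated parameters), non-normal at p < 0.05;
  skewed lesion variables are log(x+1)-transformed before comparison and
  fall back to Mann–Whitney when still non-normal.
* **Group GLMs** fit outcome ~ intercept + group dummies + age (centred)
  + sex + education by least squares; the group block is tested with a
  partial F, effect size partial η² = SS_group/(SS_group+SS_res), and
  post-hoc pairwise adjusted mean differences with 95% CIs are attached.
  Demographic (Table-1-style) subgroup tests run unadjusted; integrity
  and topography analyses adjust for age/sex/education. Both modes are
  exposed (`AnalysisPlan.adjust_demographics`).
* **Multinomial logistic regression** (Newton ML, CP reference, Wald
  95% CIs on exp(β)) handles 3-level phenotype outcomes; non-convergence
  (e.g. separation) raises a typed error and the pipeline logs the skip.
* **Backward elimination** removes the largest-p candidate until all
  remaining candidate p < 0.05 (α_stay configurable); demographic
  covariates are forced (never eliminated; also configurable).
  Standardized β = b·σ_x/σ_y with the CI on the same scale; adjusted R²
  from the final fit. Rank-deficient candidate sets shed unidentified
  terms first and the candidate matrix condition number is reported.
* **Bonferroni families** are fixed in the `AnalysisPlan` and serialized
  with every report: global CL characteristics m=2, within-network CL
  presence+fraction m=14, global integrity blocks m=2, per-network
  integrity m=7, per-domain regressions m=7. Every reported p carries its
  family size and corrected value.
* **Degenerate inputs**: identical paired vectors return t = 0 (p = 1);
  constant *nonzero* differences, zero-variance groups, singular designs
  and empty networks raise typed errors; inside the pipeline such
  comparisons are skipped with a logged reason rather than aborting the
  run.

## Recovery testing and latent labels

The study bundle stores each subject's latent phenotype alongside the
classified one. Effect-recovery checks (the CI-vs-CP non-lesional MD
excess of +0.04 confined to DMN/FPN/SMN; the VAN lesion dominance) are
evaluated against *latent* groups: rule-based classification from noisy
cognition mixes latent mildly-CI subjects (whose +0.05 MD shift is
global) into the classified CI group, which adds real but spatially
non-specific MD differences. That mixing is a property of the generative
design worth knowing about, not an implementation defect; the pipeline's
own report always uses the classified labels, as a real analysis must.

## Problem sizes

The default study (48 HC + 176 MS on the 24×24×18 grid) simulates and
analyzes in a few seconds. Calibration suites use 1000 null simulations
per test (t and F type-I error within [0.035, 0.065]); spatial-pattern
recovery uses 100 independent full studies; the acceptance script runs
one full study plus 20 recovery replicates and 100 regression-retention
replicates.

## Known limitations

* The CL "count" of a subject is the component count of the whole mask;
  merged overlapping spheres count once, so simulated counts run slightly
  below the drawn Poisson totals.
* Toy regions are small (27 voxels), so a single radius-3 lesion can
  render several regions lesional; the median lesional-region fraction is
  accordingly higher than in real cohorts at matched lesion counts.
* The multivariate ("both outcomes jointly") post-hoc model is realized
  as per-outcome least squares on the lesioned-subject subset, since
  per-outcome F statistics are what the reporting convention requires.
* Regression-based demographic adjustment of individual cognitive test
  scores is not implemented; domain Z-scores are plain HC-referenced, and
  demographic covariates instead enter every group model and (by
  default, configurable) the cognition regressions.
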