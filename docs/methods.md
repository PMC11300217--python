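# Methods

## Scope and data flow

`sparsemet` studies how to allocate a fixed phenotyping budget across a
multi-environment trial (MET) when unobserved genotype-in-environment
combinations are recovered by genomic prediction. The pipeline runs in
five stages: (1) synthetic trial generation, (2) marker QC and kinship,
(3) stage-1 adjustment of plot records to per-environment genotype BLUPs,
(4) allocation-design construction and partition sampling, (5) model
fitting and per-environment evaluation. Each stage is usable on external
data in the same TSV formats; the generator exists so the whole experiment
is reproducible without any download.

## Synthetic trial generator

The generator emulates a sugarcane-like diversity panel: 186 genotypes in
6 environments (1,116 cells), ~2,000 dosage markers (a down-sampled stand-in
for a >20k SNP panel; kinship estimates stabilise well below that),
2–3 replicates per environment, incomplete blocks carrying 3 replicated
checks.

**Markers.** Dosages are scaled allele contents on the 0–2 grid in steps
of 0.2, the coding used for high polyploids. Per marker a panel frequency
p ~ Uniform(0.05, 0.95) is drawn; genotypes sit in `n_families` families
whose frequencies drift from p by a Balding–Nichols Beta draw with
F_st = 0.15. The family structure is essential, not decorative: a panel of
unrelated genotypes has a near-identity kinship matrix, in which case the
genomic terms are statistically indistinguishable from the iid genotype
and residual terms and no information can transfer to unseen genotypes —
genomic prediction across genotypes, the phenomenon under study, would be
impossible by construction. Within-family relatedness comes out near 0.3,
typical of breeding germplasm with shared parents. Individual dosage
draws are beta-binomial with intraclass correlation 4/9, chosen so the
dosage variance equals the Hardy–Weinberg value 2p(1−p) and the VanRaden
diagonal averages ≈ 1. Missingness is independent Bernoulli at a
configurable rate.

What the generator does **not** emulate: linkage disequilibrium along a
genome, dominance/epistasis, selection, spatial field trends, crop-cycle
(plant cane vs ratoon) effects, or trait-specific marker architectures.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative design trade-offs, not real-data accuracy levels.

**Signals.** Total phenotypic variance is normalised to 1 and split by the
trait presets: SA-like (environment 47.7% of total; within-environment
shares 11.9 genotype, 34.4 genomic, 29.5 G×E, 24.2 residual) and TCH-like
(environment 80.7%; 20.9/10.8/23.5/44.8) — the decompositions observed for
sucrose accumulation and cane yield in the motivating panel. Environment
and genotype effects are iid draws; genomic values are
centered-markers × effects; G×E effects follow the reaction-norm
covariance itself (kinship-structured within an environment, independent
across environments), because iid G×E would be model-orthogonal noise that
a reaction-norm kernel should — and does — assign to the residual. Every
component is centered and rescaled so its realized (population) variance
hits the target fraction exactly in sample; total variance then matches up
to the sampling covariance between components.

**Plots.** A plot value is μ + E_j + (check effect | L_i + g_i + gE_ij) +
r_k + b_l(r) + ε. Defaults: replicate and block standard deviations 0.25
(moderate micro-environmental variation relative to the unit total),
check effects drawn with sd 0.5. Each replicate holds every test genotype
exactly once; each incomplete block carries the three checks plus test
plots, with any spare capacity filled by extra check plots. Layouts that
cannot seat all genotypes raise an error naming the deficit. The default
layout (31 blocks × 9 plots) seats 186 genotypes exactly; real trials'
plot totals depend on a check-replication scheme that is not reproduced
here.

Seeding: one experiment seed; stage generators use seed+1 (markers),
seed+2 (signals), seed+3 (plots), seed+4 (cell-level noise), so stages are
individually reproducible.

## Marker QC and kinship

Filters drop markers with minor allele frequency below 3% (a MAF of
exactly 0.03 is retained — "below" is read strictly) or more than 50%
missing dosages, with p̂ = mean dosage / 2; read-level QC (Phred, depth,
marker spacing, biallelic checks) acts on variant calls and is out of
scope. Missing dosages are mean-imputed per marker. The kinship is
VanRaden's K = WW′ / Σ 2p̂(1−p̂) with W column-centered dosages, applied
verbatim to fractional dosages (no polyploid-specific variant), plus a
configurable 1e-6 diagonal ridge for downstream invertibility. Exactly the
genotypes present in the input matrix enter K.

## Stage-1 adjustment

Per environment, y_ikl = μ + Check + L_i + r_k + b_l(r) + ε with the
intercept and per-check indicators fixed and L, r, b(r) independent random
effects. Check plots carry no genotype effect (checks are excluded from
the prediction panel). REML is maximised over log-variances with L-BFGS-B;
the likelihood is evaluated through the Woodbury identity in
random-effect coordinates, so the cost is cubic in the number of effect
levels (~300) rather than plots. The response is centered before fitting
to avoid cancellation; the intercept absorbs the shift. BLUPs are returned
as deviations without the intercept — stage-2 models carry their own mean
and environment effects, so per-environment centering is harmless (Pearson
accuracy within an environment is invariant to it). One value per plot is
assumed; if a trial measures several crop cycles, average or pick one
before adjustment. Non-convergence raises with the optimiser trace rather
than returning a silent fit.

## Designs and partitions

`enumerate_grid` builds the experiment grid: calibration sizes
186…72, and per size the maximal-A design plus A descending through
multiples of 4 to zero. `sample_partition` shuffles genotypes with the
given seed, slices A·T of them into T disjoint single-environment groups,
assigns the next B to all environments, then samples the prediction set
uniformly from non-calibration cells. The prediction set is fixed at 930
cells across all designs so comparisons share a common target; at reduced
calibration sizes the remaining cells are "unused". Within a replicate the
same partition is shared by all models. Replicate seeds are
base_seed × 1000 + replicate. NOG and OG pools are disjoint, and NOG
assignments are resampled independently per design. Optimised (non-random)
training-set selection is out of scope — allocation is randomised by
design.

## Prediction models

Kernels over the n = G·T cell grid: K_E = Z_E Z_E′, K_L = Z_L Z_L′,
K_g = Z_L G Z_L′, K_gE = K_E ⊙ K_g, plus the identity residual. Each
kernel is represented exactly by a column-space factor X with XX′ = K:
the incidence matrices themselves for E and L, Z_L·chol(G) for g, and the
per-environment masking of that factor for gE. This is equivalent to the
usual eigen-representation of kernel regression but needs no eigenvalue
truncation and preserves the kernels' exact zero/block structure (so, for
example, a genotype with no observations contributes exactly zero L
effect).

The Gibbs sampler updates, per iteration: the intercept (flat prior); per
kernel a *joint* draw of its factor-space effects from the conjugate
normal — diagonalised once per fit via an eigendecomposition of
X_obs′X_obs, making every subsequent draw a pair of matrix–vector
products; then scaled-inverse-χ² variance draws. Priors use df₀ = 5 and
scales set so each prior mode equals var(y)·R², with R² = 0.5 split
equally across kernels and 0.5 for the residual — the convention of
standard Bayesian kernel-regression software. Defaults are 12,000
iterations, 2,000 burn-in, thinning 5 (2,000 retained samples). No
convergence diagnostics are enforced; seeds and retained counts are
recorded in the fit.

Point predictions are Rao-Blackwellised: at each retained iteration the
*conditional mean* of each effect block (given everything else) is
accumulated rather than the sampled value. This is an unbiased estimator
of the same posterior mean with much lower Monte-Carlo noise, and it makes
structural zeros exact — under a CV1 partition, M1's predictions are
constant within an environment rather than constant-plus-noise. Variance
components are posterior means of the sampled values. Unobserved cells
get predictions through the full-grid factors at no extra cost.

`blup_oracle` provides the closed-form GLS/BLUP solution at fixed variance
components and serves as the independent check of the sampler (agreement
to RMS ≤ 0.02 on a 36-cell toy at 50k iterations, with error decreasing in
chain length).

Marker-effect parameterisations (Bayes-alphabet), non-additive kernels and
multi-trait models are out of scope.

## Evaluation

Pearson correlation and MSE are computed per environment over that
environment's prediction cells. A correlation is *undefined* — reported as
missing, never zero — when either side is constant; constancy is detected
with a near-machine-precision relative spread threshold (1e-8) so that the
exactly-constant M1/CV1 case is caught even after float accumulation.
Across-environment and across-replicate summaries average the defined
values and report how many were defined. Variance decomposition from a
full-data fit reports 100·σ²_k·d̄_k / Σ per term, where d̄_k is the mean
kernel diagonal (the exact variance contributed by a N(0, σ²K) effect;
d̄ = 1 for standardized kernels); within-environment shares renormalise
after removing the environment term. Terms absent from a model are
omitted and the rest renormalised.

## Numerical choices and degenerate inputs

- Kinship Cholesky retries with jitter up to 1e-6 before declaring a
  kernel non-PSD.
- Variance draws are strictly positive (χ² in the denominator), so fitted
  components never collapse to exactly zero; fixed components may be zero
  except the residual.
- Filtering away every marker warns (`EmptyMarkerWarning`) and returns an
  empty matrix rather than failing silently; fully missing markers and
  monomorphic-only panels raise.
- A single-environment simulation sets the environment effect to zero (it
  is not separable from the intercept).
- Design arithmetic rejects A+B = 0 (mean replication undefined) and
  calibration sizes not divisible by T.

## Problem sizes used in the test suite

Tests run the full 1,116-cell analyses where the claim is about the full
grid (variance-fraction recovery over 5 seeds, the CV1 contrast) and
reduced panels elsewhere (30–100 genotypes, 200–500 markers; the design
trend uses 50 genotypes with 2 replicate partitions over 5 seeds). These
sizes were chosen as the smallest at which the Monte-Carlo variability of
each check is comfortably below its assertion margin.
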