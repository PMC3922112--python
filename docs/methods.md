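# Methods

## Model

For n individuals with adjusted phenotype vector **y**, the mixed linear
model is

    y = Xβ + g + ge + ε,
    V = Var(y) = A_g σ²_g + A_ge σ²_ge + I σ²_ε,

where **g** holds the aggregate additive effects of all autosomal SNPs,
**ge** the genotype–environment interaction effects, and X carries an
intercept plus indicator columns for the environmental factor under
test. A_g is the realized genetic relationship matrix (GRM)

    A_jk = (1/N_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

with x the dosage of the counted allele, p_i its sample frequency, and
N_jk the number of SNPs non-missing in both members of the pair. A_ge
equals A_g for same-environment pairs (including the diagonal) and 0
across environments; this encodes the assumption that interaction
effects are genetically structured within an environment and uncorrelated
between environments. The reported quantities are the proportions
σ²_g/σ²_p ("V_G/V_P", SNP heritability) and σ²_ge/σ²_p ("V_GE/V_P"),
with σ²_p the sum of the fitted components.

One environmental factor enters per fit; area, sex, and birth-year band
analyses are three separate models. Phenotypes are pre-adjusted (OLS on
age, z-scored within area × sex strata), which is why area and sex need
not re-enter the fixed effects; the factor indicator is kept in X anyway
as cheap insurance against unbalanced simulated data.

## Estimation

Variance components are estimated by average-information (AI) REML. The
restricted log-likelihood (constants dropped) is

    logL = −½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy ],
    P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹.

Each iteration computes the gradient −½[tr(P V_k) − yᵀP V_k P y] and the
average-information matrix ½ yᵀP V_k P V_l P y, then updates by a Newton
step with these safeguards:

- **First step is EM** (robust far from the optimum); afterwards AI.
- **Active set**: a component pinned at its floor with an outward
  gradient is held fixed and the AI system is solved over the free
  components only. Without this, the projected Newton step near a
  boundary points in the wrong direction for the free components and the
  iteration stalls.
- **Monotone guard**: a candidate step (AI at step sizes 1, ½, …, 1/16,
  then EM) is accepted only if it does not decrease the restricted
  likelihood, checked with a single extra Cholesky factorization. This
  makes logL(full) ≥ logL(reduced) hold by construction up to
  convergence tolerance.
- **Floor**: components are constrained to ≥ 10⁻⁶ σ²_p, so a boundary
  estimate prints as ~10⁻⁶ rather than a negative value.

Starting values split the observed phenotypic variance equally
(σ²_p/(K+1) per component); convergence requires a relative logL change
below 10⁻⁸ and component changes below 10⁻⁶ σ²_p, with a 100-iteration
cap and an explicit non-convergence flag. Standard errors come from the
inverse AI matrix; proportion SEs by the delta method. A singular or
ill-conditioned AI matrix (e.g. A_g = I, where σ²_g and σ²_ε are not
separately identifiable) is reported as a flat likelihood direction.

On instances small enough to enumerate (n ≤ 25), the estimates are
checked against a dense grid search (step 0.005) of the profile-scale
restricted likelihood over the proportion simplex — an oracle
implemented independently in the test suite.

## Significance of a variance component

The interaction component is tested by the likelihood ratio between the
full model and the model without A_ge. Because σ²_ge = 0 lies on the
boundary of the parameter space, the null distribution of the statistic
is the 50:50 mixture of a point mass at 0 and χ²₁: p = ½·P(χ²₁ ≥ LRT),
and p = 0.5 exactly when the statistic is 0. A marginally negative
statistic (optimizer noise) is clamped to 0 with a warning. Family-wise
control across traits × factors uses Bonferroni, α divided by the number
of fits, computed from the configuration rather than hard-coded.

## Bivariate model and genetic correlation

To ask whether the *same* genetic signals act in two environments, the
trait is split into two traits on disjoint individuals (one per
environment). The covariance model has per-environment genetic variances
σ²_g1, σ²_g2, a cross-environment genetic covariance σ_g12 carried by
the between-environment blocks of the GRM, and per-environment residual
variances; residual covariance is structurally absent because no
individual is observed in both environments. The fit is the same AI-REML
machinery over five components with the feasibility constraint
|σ_g12| ≤ √(σ²_g1 σ²_g2) enforced by projection; r_g = σ_g12/√(σ²_g1 σ²_g2)
is derived, never directly parameterized, so it lies in [−1, 1] by
construction. Its SE comes from the delta method.

Null hypotheses about r_g are tested by refitting under the constraint:
r_g = 0 drops the covariance component (an interior null, χ²₁
reference); r_g = ±1 reparameterizes σ_g12 = r₀√(σ²_g1 σ²_g2) and
maximizes the four remaining log-variances numerically (Nelder–Mead on
the directly evaluated restricted likelihood). The r_g = 1 null sits on
the correlation boundary, so its χ²₁ reference is conservative; the
output notes this. A Wald test from the SE would be the main
alternative; the LRT was chosen because it respects the [−1, 1]
constraint near the boundary where the Wald quadratic approximation is
poorest.

## Per-SNP scan and norms of reaction

The locus-level complement fits, per SNP, OLS of the adjusted phenotype
on dosage separately in the two strata and compares slopes:
z = (b₁ − b₂)/√(se₁² + se₂²), referred to the standard normal — the
convention of the PLINK gxe test; at cohort sample sizes the difference
from a t reference is negligible. The pooled single-regression slope
t-test supplies the main-effect p-value. Missing dosages are dropped per
SNP per stratum; a stratum with < 3 informative samples or constant
dosage flags the record instead of producing a number.

Norms of reaction emulate genotype replication in a species where none
is possible: individuals are ranked by their number of GRM partners
above a threshold (default 0.020, strict inequality), the top k (default
3) become hubs, each hub plus its partners forms a genotype group, and
anyone appearing in two or more groups is excluded from all of them —
groups are therefore disjoint by construction. Hub ranking is a single
global ranking; ties keep input order. The summary is the mean ± SEM of
the adjusted phenotype per group × environment cell; parallel profiles
across environments indicate no interaction. A locus-specific variant
tabulates the 3 × 2 genotype-class × environment cell means.

## Synthetic cohorts

The generator is the sampling counterpart of the fitted model. Per SNP a
frequency is drawn uniformly on [maf_low, maf_high] (default
[0.05, 0.5]) and dosages as binomial(2, p) — no linkage disequilibrium.
Phenotypes are built from standardized dosages z (using the generating
frequency) as

    y_j = Σ_i z_ij u_i + Σ_i z_ij v_i(env_j) + Xβ + ε_j,

with u_i ~ N(0, h²_g/m), v_i(e) ~ N(0, h²_ge/m) drawn independently per
environment level, and ε_j ~ N(0, 1 − h²_g − h²_ge). Independent
per-environment deviations are the simplest parameterization whose
induced covariance is exactly A σ²_ge within an environment and 0
across — the masking rule the estimator assumes. The bivariate generator
instead draws per-SNP effect *pairs* from a bivariate normal with
correlation r_g and uses the effect vector of each individual's own
environment. Downstream, the GRM standardizes by *sample* frequencies
while the generator used the true ones; the small mismatch is accepted
as realistic.

Defaults are the desk-scale stand-in for the targeted study design:
n = 2000 individuals, m = 2000 SNPs, two areas at 40/60 (echoing a
rural/urban imbalance), two sexes, three birth-year bands (1931–45,
1946–55, 1956–63). At this scale the per-pair GRM information
(n²/m) exceeds the cohort-scale original, so replicate-mean REML
estimates are precise enough for recovery tests in minutes. For the
bivariate recovery runs the per-environment heritability is fixed at
0.30 — a typical SNP-heritability magnitude for anthropometric traits —
since only the correlation, not the variance level, is the target of
those runs. Randomness flows from one root seed through fixed-offset
child streams (genotypes, environment assignment, effects, residuals,
covariates), so stages can be rerun independently and identical
configurations are bit-identical.

A relative-pair spiker rebuilds one row of a pair by copying each of the
partner's alleles with probability c (resampling from the allele
frequency otherwise), giving an expected relationship ≈ c; it provides
test material for the pruning rule. Note that with sizable related
clusters, sample-frequency centering deflates realized within-cluster
GRM entries below c (the cluster drags the frequency estimate), which
desk-scale tests must account for when placing thresholds.

## What the validation shows — and does not

Recovery tests demonstrate that the estimator is calibrated *under its
own model*: unlinked SNPs, normally distributed per-SNP effects,
Gaussian residuals, a single cleanly measured environmental factor, and
interaction covariance that follows the masking rule exactly. Passing
them does not establish robustness to linkage disequilibrium structure,
MAF-dependent architectures, population stratification, shared
environment within families, or measurement error in the environment —
all of which affect real-cohort estimates. The exact worked statistics
(boundary-mixture p-values, Bonferroni thresholds, hand-computed GRM
entries, the Hardy–Weinberg enumeration) are model-free and checked to
print precision.

## Numerical and design notes

- The GRM diagonal uses the same estimator formula as the off-diagonal;
  the distinct diagonal estimator used by some tools is deliberately not
  adopted, so diagonals have mean ≈ 1 under random mating but are not
  shrunk.
- Sample-frequency centering forces the off-diagonal GRM mean to
  −mean(diag)/(n − 1); tests assert around that value, not around 0.
- Relatedness pruning is greedy hub-first: repeatedly drop the
  individual in the most above-cutoff pairs (ties: the latest in input
  order, so the earlier member of a tied pair is kept), which maximizes
  the retained sample in the structures that matter here. With fewer
  than 2 individuals left the call is an error.
- The marker QC threshold "missingness > 5%" is strict; MAF and
  Hardy–Weinberg are computed on non-missing genotypes over all samples;
  monomorphic SNPs fall to the MAF filter. Filters are attributed in the
  fixed order missingness → MAF → HWE.
- The Hardy–Weinberg test is the two-sided exact conditional test
  (enumeration over heterozygote counts with a stable recurrence), not
  chi-square, and without a mid-p correction.
- Age enters adjustment as a supplied numeric column; in simulated
  tables it is derived from birth year. Out-of-band birth years are
  binned by the same arithmetic with a warning rather than rejected.
- The `.grm.gz` text format (lower triangle with per-pair SNP counts,
  plus an id file) is written for interoperability with the GCTA
  ecosystem.
- Desk-scale caveat: GRM entries have sd ≈ 1/√m, so cohort-scale
  relationship cutoffs (0.025, 0.020) are meaningful only when m is
  large; small-m configurations must raise them above the noise band, as
  the pipeline tests do.
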