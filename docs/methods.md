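# Methods

This note documents the models, numerical choices and known limits of
the `ddx` package.  Nothing here is an empirical claim beyond what the
test suite and `scripts/acceptance.py` compute.

## Differential association model

For a biallelic SNP with per-allele log-odds ratios `β₁` (disorder A vs
controls) and `β₂` (disorder B vs controls), the case-case contrast has
`β_diff = β₁ − β₂` with variance `SE₁² + SE₂² − 2 r SE₁ SE₂`.  The
derivation assumes the two studies' controls come from the same
population so the control terms cancel; heterogeneous control
populations (e.g. different ancestries) bias the estimate.  The
correlation `r` of the two estimates under the null is taken from the
cross-trait LD-score-regression intercept, or supplied directly.  For
two case-control studies sharing only controls it equals

```
r = N_shared · sqrt(P₁P₂/((1−P₁)(1−P₂))) / sqrt(N₁N₂)
```

with `Pᵢ` the case fractions (`ddx.simulator.expected_overlap_intercept`).
A user-supplied `r` always wins over an estimated one (a warning is
logged).  Two-sided p-values come from the normal distribution with no
finite-sample correction — summary-statistic sample sizes are large.

Genomic control divides the χ² statistics by `λ`, taken from the LDSC
intercept of the differential statistics, from `median(χ²)/0.4549`, or
from the user.  `λ` is clamped at 1 (no deflation), and affects only
the reported `P_GC`; heritability fits consume the uncorrected χ².

## Harmonization

Trait 1's effect-allele orientation wins.  Swapped allele pairs flip
the sign of trait 2's beta and complement its allele frequency; strand
complements are relabelled first.  Strand-ambiguous A/T and C/G SNPs
are dropped by default because their orientation is unresolvable
without frequency information; the optional `keep_if_eaf_informative`
policy retains them when both studies report frequencies outside
0.5 ± 0.08 (window configurable) and orients trait 2 by frequency side.
SNPs are joined on ID, not position; position disagreement only warns.
Harmonization is idempotent, and every input SNP lands either in the
pair or in the drop log.

Continuous-trait statistics (standardized phenotype, linear scale) are
converted to case-control scale by a threshold model: with the top
fraction `q` as cases and `T = Φ⁻¹(1−q)`, `β_bin = β_cont·φ(T)/(q(1−q))`
and `z_bin = z_cont·φ(T)/√(q(1−q))` (the asymptotic efficiency of
dichotomizing a normal trait).  This is this package's own stated
conversion, validated against a logistic-regression simulation at
n = 10⁶ (5% tolerance); exact finite-sample algebra is not attempted.

## LD-score regression

Univariate: weighted least squares of `χ²_j` on `N_j ℓ_j / M` with
intercept; the slope is the observed-scale h².  Weights
`1/(2(1 + N h² ℓ/M)² ℓ)` are refined twice from an unweighted fit.
The conventional outlier filter `χ² ≤ max(80, 0.001 N)` is on by
default and disabled for simulated panels.  Negative slopes are
reported as-is with a warning.  Cross-trait: `z₁z₂` on
`√(N₁N₂) ℓ_j / M`; the intercept estimates the null test-statistic
correlation, the slope the genetic covariance;
`r_g = gencov/√(h²₁h²₂)` is reported as-is even outside [−1, 1].
Standard errors come from a delete-a-block jackknife over
position-contiguous blocks (200 blocks, or `max(2, n/10)` below 2000
SNPs).

With unit LD scores (independent simulated SNPs) slope and intercept
are collinear, so the univariate fit constrains the intercept to its
null value 1 — closed form `h² = (mean χ² − 1)·M/N` — and the
cross-trait fit reports `mean(z₁z₂)` as the intercept with no
covariance estimate.  In this mode a polygenic signal shared between
the traits would leak into the intercept; the simulator therefore
defaults to the analytic overlap formula above for `r`.

Liability conversion uses the standard transformation with the
population prevalence `K` and sample case fraction `P`.  For the
differential pseudo-trait the conventions are `K = K_A/(K_A+K_B)`
(conditioning on having exactly one disorder) and `P` the case fraction
of the constructed contrast; this choice reproduces the printed maximum
AUCs checked in the acceptance tests.

## Liability-threshold prediction machinery

The differential-diagnosis model conditions on exactly one of the two
disorders being present: prevalence of the "case" state
`K = K_A/(K_A+K_B)`, threshold `T = Φ⁻¹(1−K)`, score `G ~ N(0, v)`,
risk `Φ((g−T)/√(1−v))`.  AUC is `P(G_case > G_control)` integrated on a
20001-point grid over ±8 SD of the score (trapezoid rule; the grid
densities are renormalized, which holds `E[risk(G)] = K` to 10⁻⁴ and
agrees with a 10⁷-draw Monte-Carlo within 0.002).  A closed-form normal
approximation is carried as a cross-check and agrees within 0.005 over
`v ≤ 0.5`, `K ∈ [0.01, 0.5]`.  `invert_auc` brackets `v` by Brent's
method to 10⁻⁶ in AUC.

Percentile risks are point values at the percentile
(`g_q = √v·Φ⁻¹(q)`); a bin-average mode is provided, and its top/bottom
relative risks are systematically *larger* than the point version
because the tail bins extend beyond the percentile points.  In the
two-disorder setting the control-disorder risk is one minus the
case-disorder risk by construction.

## Polygenic-score forecast

The marginal density of the differential z-scores is estimated by
Lindsey's method: histogram counts in 199 equal-width bins spanning the
data ± 0.1, modelled as Poisson with a log-linear natural cubic spline
(7 df, knots at equally spaced data quantiles, boundary knots at the
data range).  Tweedie's formula gives the posterior mean
`E[μ|z] = z + d/dz log f̂(z)` and variance `1 + d²/dz² log f̂(z)`
(unit sampling variance).  If the Poisson fit fails, a zero-mean normal
fit (`z_post = z(s²−1)/s²`) is substituted with a warning.

For each of the 18 conventional p-value thresholds, the forecast
variance explained on the observed scale is the posterior signal energy
of the selected SNPs, `Σ E[μ²|z] / n_eff`, with
`n_eff = 4/(1/N_case + 1/N_control)` of the differential contrast.
Using the posterior *second moment* rather than the squared posterior
mean makes the summed energy an unbiased estimate of `Σμ²`; individual
variance terms are left unclipped so that their estimation noise
cancels in the sum (clipping at zero would bias a null panel upward).
The energy converts to the liability scale and to an AUC through the
machinery above.  Greedy pruning (keep the most significant SNP of any
pair with r² > 0.1 within 1 Mb) stands in for LD clumping; independent
panels pass through.

Known limitation: the forecast maps variance explained through a
*single*-liability threshold model, while a cohort of single-disorder
subjects is conditioned on two liabilities (disorder A present, B
absent, or vice versa).  That two-sided conditioning separates the
groups slightly more than the single-liability model predicts, so at
strong differential signal (liability variance ≈ 0.3, as under the
simulator's defaults) the forecast sits ≈ 0.03–0.04 below the realized
AUC even when the true effects are supplied.  The bias vanishes as the
signal weakens toward the regime of current real GWAS (AUC ≲ 0.7).

## Simulator

Study conditions (defaults): 300 independent biallelic SNPs, allele
frequencies Uniform(0.05, 0.95); two disorders with prevalence
K = 0.10 each; liability-scale SNP heritabilities 0.2 (A) and 0.3 (B);
SNP classes shared-equal / A-specific / B-specific / null at 25% each;
expected cases per disorder 10,000 (population = ncases/K); 15% of each
study's sample shared between the two control pools; 30 replicates.

Per-SNP effects are Gaussian draws rescaled so each trait's squared
effects sum exactly to its h² ("random" allocation; an "equal"
allocation is available).  The heterogeneous per-SNP variances make the
squared differential effects approximately chi-square distributed,
which is what produces the slow growth of power with sample size that
a validation of this kind exhibits; equal effects would drive power to
1 almost immediately.  Shared SNPs carry identical effects on both
disorders and are null for the differential test, as are the null
class; power is evaluated over the trait-specific classes.

Disease states follow liability thresholds with independent
environmental residuals; the shared genetic component induces a
liability correlation ≈ 0.1 and hence ≈ 15% comorbidity among cases.
With comorbidity disabled, each study's cases are its disorder's
single-disorder subjects (comorbid subjects are excluded, and the
direct case-vs-case GWAS compares exactly the same A-only and B-only
pools).  Controls are screened (neither disorder); each study takes all
its cases plus `2N − n_cases` controls, `N` being the larger case
count, and the two control pools share `round(P·2N)` subjects.
Per-SNP logistic regressions (vectorized Newton/IRLS, no covariates,
verified against statsmodels to 10⁻⁶) produce the summary statistics.

The "expected" per-allele log-odds used as ground truth for
unbiasedness checks is computed from the three genotype classes under
Hardy–Weinberg with ascertainment-shifted log-odds and
information-weighted least squares (`expected_logodds`).

What the simulator does *not* emulate: linkage disequilibrium between
SNPs (the validated statistic is per-SNP, so LD affects multiplicity,
not validity), covariates and stratification, ascertainment beyond the
stated sampling, and rare variants.  Passing tests therefore certify
the estimator's algebra and calibration, not robustness to population
structure.

Problem sizes in the test suite and acceptance script — 30 replicates
at 10,000 and 20,000 expected cases, 35 replicates for null
calibration at 2,000, 20 replicates for the forecast check — were
chosen to keep Monte-Carlo error comfortably below the tolerances
while the whole suite stays desk-scale.

## Determinism

Every stochastic routine takes a `numpy.random.Generator` or a seed;
replicate streams are spawned from a single `SeedSequence`, so a given
(seed, config) pair reproduces outputs byte-identically.  CLI outputs
are written atomically (temp file + rename) and each run leaves a JSON
provenance record (config, seed, library versions, input checksums).
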