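# Methods

`longmi` is a simulation laboratory for a question that arises routinely in
longitudinal epidemiology: when a continuous time-varying exposure with a
*non-linear* trajectory over time has missing values, how well do the
standard multiple-imputation (MI) strategies — fully conditional
specification (FCS), multivariate normal imputation (MVNI) and the two-fold
FCS algorithm — recover a lagged exposure–outcome association, compared
with a complete-case analysis?  The package implements the whole loop:
data generation, missingness imposition, imputation, target analysis and
performance scoring.

## The data-generating model

Each simulated cohort follows `n` children over five waves, two years
apart, from roughly age 4¾.  The motivating substantive question is the
association between BMI-for-age z-score (`bmiz`, the exposure) and a binary
sleep-problem indicator (the outcome).

**Time-invariant covariates.** Sex ~ Bernoulli(0.49); maternal age ~
Normal(31, 5²) years truncated to [18, 45]; birthweight ~ Normal(3.30 +
0.12·[male], 0.55²) kg truncated to [1, 6]; maternal education (completed
vs not) logistic in maternal age; maternal smoking logistic in education.
The chain encodes the dependencies: education rises with maternal age,
smoking falls with education, birthweight differs by sex.  These marginals
are configuration (`TimeInvariantParams`), chosen as plausible for an
Australian birth cohort; nothing downstream depends on their exact values
beyond realism.

**Wave-1 outcome.** Logistic in education, sex, birthweight and maternal
age, with the intercept calibrated (root-finding on the expected
proportion) so prevalence is 0.15.

**Exposure trajectory.** A linear mixed model: population quadratic in age
(months) plus covariate effects, a person-level random intercept and random
linear and quadratic age slopes (trivariate normal), and iid residual noise
(SD 0.45).  Defaults: age coefficient 0.015/month, quadratic −5×10⁻⁵/month²
(so the mean trajectory rises and flattens over ages 4–13, the non-linearity
that motivates the comparison), random-intercept SD 0.85, random-slope SDs
0.004 and 10⁻⁵ with corr(intercept, slope) −0.3.  The intercept is
calibrated so mean exposure at wave 1 is 0.30 (closed form — the model is
linear in the intercept).

**Follow-up outcomes.** For waves 2–5, sequentially logistic in the
*previous* wave's exposure (coefficient λ₁ = log OR, the estimand; stored
as the exact log of 1.1 or 1.5, not the rounded 0.1/0.4), the covariates
and the previous wave's outcome (coefficient 1.2, giving realistic
within-child outcome tracking).  The intercept is calibrated so the
average prevalence over waves 2–5 is 0.15; the calibration propagates the
previous-outcome distribution exactly (a two-state forward recursion per
child), so no simulation noise enters the root-finding beyond the fixed
reference sample of 100 000 covariate/trajectory draws.

Because the target GEE uses exactly the columns of the follow-up model
(same lag structure), λ₁ is the true value of the analysis parameter —
the analysis model is congenial with the generator by construction.

## Missingness

Only the exposure at waves 2–5 is ever masked; wave 1 and all other
variables stay complete.  Cumulative missing targets grow linearly to the
final-wave proportion (0.25 or 0.50), and each wave's target mass is split
half-and-half between two patterns (configurable via `dropout_share`):

* **Model A — dropout**: logistic model for becoming missing at wave j+1
  and every later wave;
* **Model B — intermittent**: logistic model for being missing at wave
  j+1 only, applied only to current non-dropouts.

Under MAR both models' log-odds depend on the outcome at waves 1 and 5 and
on maternal smoking, with odds ratios 1.67/1.64/1.61 (model A) and
1.61/1.58/1.58 (model B) in the weak scenario and their squares (to
2-decimal rounding: 2.80/2.70/2.60 and 2.60/2.50/2.50) in the strong
scenario.  MCAR uses the same two-pattern machinery with intercept-only
models.  Intercepts are re-solved per dataset by monotone root-finding on
the *expected* proportion given the realized covariates, so the target
fractions are met at each wave up to binomial noise (within ~0.01 at
n = 5000).  Dependence on the wave-5 outcome is what makes the
complete-case analysis biased under MAR: conditioning on completeness
selects on the outcome.

## Imputation engines

All three methods impute only the four incomplete exposure columns, so
every univariate model is linear-normal and the binary variables act as
complete predictors (MVNI's joint-normality assumption therefore bears only
on the imputed variables).  Holes are initialized by random draws from the
variable's observed margin.  Each of the `m` imputations runs on an
independent RNG substream, so results do not depend on execution order.

The common primitive is a proper Bayesian linear-regression draw: σ*² from
the scaled inverse-χ² posterior, β* from N(β̂, σ*²(XᵀX)⁻¹) under the
noninformative prior, imputations as X_mis β* + N(0, σ*²) noise.  A
trace-scaled ridge (10⁻⁸) stabilizes near-collinear designs; an exactly
rank-deficient design (relative eigenvalue below 10⁻¹⁰) raises an error
naming the offending predictors rather than imputing garbage.

* **FCS** treats each wave's exposure as a distinct variable and cycles
  (default 10 passes) over the incomplete waves, regressing each on the
  exposure at all other waves (current values), the outcome at all five
  waves, and the time-invariant covariates including the auxiliary
  maternal smoking.
* **MVNI** fits one joint multivariate normal to all 15 analysis and
  auxiliary columns by data augmentation: I-step draws the missing cells
  from their conditional normal given the observed cells (vectorized per
  missingness pattern), P-step draws (μ, Σ) from the
  normal–inverse-Wishart posterior.  A single chain is run; imputations
  are saved every `da_thin` iterations after `da_burnin` (defaults
  100/200).  Because only four well-identified columns are incomplete, the
  chain mixes quickly and these defaults are conservative.
* **Two-fold FCS** restricts the model for wave t to the exposure and
  outcome at waves within `window_width` of t (truncated at the panel
  boundaries) plus all time-invariant variables, sweeping time points in
  order `twofold_among` times with `twofold_within` cycles each.  With
  width 4 the window covers every wave and the predictor set equals FCS's,
  which the tests exploit as an equivalence check.  Window width 1 cannot
  see the curvature of the trajectory beyond adjacent waves — the
  mechanism behind its slight residual bias.

Child age is excluded from all imputation models: it is near-deterministic
by design and the imputation models are specified in terms of the analysis
variables plus the auxiliary variable.  Iteration counts are conventional
choices (the methods' sources do not pin them); all are configurable.

## Target analysis and pooling

The estimand is the population-average log-odds ratio of the wave-j outcome
per unit of wave-(j−1) exposure, j = 2…5, adjusting for education, sex,
birthweight, maternal age and the previous outcome.  It is estimated by GEE
with logit link, an unstructured 4×4 working correlation and robust
sandwich standard errors; 95% CIs are Wald.

`fit_gee` is a vectorized Fisher-scoring solver specialized to balanced
four-row clusters.  The working correlation is common to all clusters, so
each update needs a single 4×4 inverse and BLAS-level batched products;
a fit on 5000 clusters takes tens of milliseconds, which is what makes
replicate × imputation × method grids tractable on one core.  The solver is
cross-checked against statsmodels' generic GEE in the test suite
(coefficients to ~10⁻⁵, robust SEs to ~10⁻⁴ relative).  The β–correlation
fixed point contracts slowly on small, strongly correlated samples, so the
iteration budget is generous (500) with a step tolerance of 10⁻⁶; fits
that still fail are flagged, excluded from summaries and counted.  If the
moment estimate of the unstructured correlation loses positive
definiteness the solver falls back to exchangeable for that fit and flags
it.

Complete-case analysis drops a child entirely if the exposure is missing
at any of waves 2–4; the wave-5 exposure never enters the lagged analysis,
so its missingness is irrelevant to retention.

MI estimates are combined by Rubin's rules: pooled estimate = mean; total
variance T = W + (1 + 1/m)B; CI from the t distribution with Rubin's
classic (1987) degrees of freedom, (m−1)(1 + W/((1+1/m)B))².  At the
study's cluster counts the small-sample Barnard–Rubin correction would be
indistinguishable; the classic df is used and documented here.

## Performance metrics

Per scenario × method cell, across replicates: absolute bias
|mean(est) − λ₁|; relative bias 100·bias/|λ₁|; empirical SE (SD of
estimates, ddof 1); model-based SE (mean of estimated SEs); coverage (% of
95% CIs containing λ₁); RMSE = √(bias² + empirical SE²), chosen so the
bias/variance identity holds exactly (it differs from √mean-squared-error
only by the variance denominator convention); Monte-Carlo error =
empirical SE/√R.  Bias is reported as a magnitude, with the signed value
retained for diagnostics.

## Study orchestration and reproducibility

A scenario is (mechanism, final proportion, true OR).  Replicate r of a
scenario derives its seed from the master seed and the scenario identity
only — never from which methods are enabled — so methods are always
compared on identical incomplete datasets (paired comparisons).  All
randomness flows through numpy `SeedSequence` substreams: per stage within
the generator, per imputation within a method.  Identical configuration
and master seed give bit-identical outputs.  Scaled-down runs (smaller n,
fewer replicates, smaller m) traverse exactly the same code path as
full-scale runs.

## Problem sizes used by the shipped checks

The full design (1000 replicates × 5000 children × 50 imputations × 12
scenarios × 5 methods) is a cluster-scale job.  The shipped checks use
desk-scale versions chosen a priori, with Monte-Carlo allowances computed
from the run's own empirical SEs rather than tightened or loosened after
the fact:

* acceptance script: cohorts of 2000, 100 replicates per scenario for the
  five-method grid, m = 5, MVNI burn-in 100/thin 25; the three
  complete-case bias cells at 25% missingness additionally run a
  1000-replicate complete-case-only extension (the grid's replicates are a
  prefix of the same paired stream), because those cells are read on a
  0.02 log-odds scale where 100-replicate simulation error would dominate;
* test suite: cohorts of 800–1500 for unit tests, 40 replicates × 1000
  children for the end-to-end criteria, with bias thresholds widened by
  twice the simulation SE and coverage bands by three binomial SDs at the
  replicate count actually run.

## What the generator does and does not emulate

It reproduces the statistical skeleton of a real child cohort: quadratic
individual growth curves with correlated random effects, outcome tracking
over waves, covariate dependencies, calibrated prevalences, and missingness
with both monotone and intermittent patterns driven by observed outcomes.
It does not emulate: measurement error or the LMS construction of z-scores
from raw BMI (z-scores are generated directly); attrition in variables
other than the exposure; non-normal exposure residuals; informative
(MNAR) missingness; or unbalanced visit schedules.  Conclusions from
passing tests therefore speak to the methods' behavior under a
well-specified MAR world with a congenial analysis model, not to every
real-data complication.

## Known limitations

* The generating coefficients are this package's documented defaults, not
  estimates from any real cohort, so metrics that depend on their exact
  values (the magnitude of complete-case bias under MAR, empirical SEs)
  are reproducible here but approximate relative to any external report.
* The GEE solver handles balanced four-row clusters only (all it ever
  sees here); it is not a general GEE replacement.
* MVNI uses a single DA chain; between-imputation independence relies on
  the thinning interval, which is ample for this missingness structure but
  should be revisited if many more columns were incomplete.
* Rubin's classic df can exceed m − 1 substantially; for very small m and
  tiny samples the Barnard–Rubin correction would matter.
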