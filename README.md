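# longmi

Simulation toolkit for evaluating multiple-imputation (MI) methods when a
**continuous time-varying exposure with a non-linear trajectory over time**
has missing values in a longitudinal study.

## The problem

Longitudinal cohorts collect the same variables over repeated waves, and
missing data accumulate wave by wave.  The standard MI strategies — fully
conditional specification (FCS, "chained equations") and multivariate
normal imputation (MVNI) — treat each wave's measurement as *just another
variable*.  The two-fold FCS algorithm instead imputes each time point
from a window of adjacent time points, trading information for stability.
When the incomplete variable follows a non-linear (here quadratic-in-age)
trajectory, a narrow window may not see the curvature, and a complete-case
analysis (CCA) may be badly biased whenever missingness depends on
observed outcomes.

`longmi` provides a complete, reproducible laboratory for this question,
modeled on a five-wave child cohort: BMI-for-age z-score (`bmiz`) is the
exposure, a binary sleep-problem indicator the outcome.

## The model

For child *i* at wave *j* (ages ~4¾ to ~13 y, waves two years apart):

* exposure (linear mixed model, quadratic in age with random effects):

  `bmiz_ij = (θ0+a0i) + θ1·sleep1_i + (θ2+a1i)·age_ij + (θ3+a2i)·age²_ij + covariates + ε_ij`

* outcome (sequential logistic, waves 2–5):

  `logit Pr(sleep_ij = 1) = λ0 + λ1·bmiz_i,j−1 + covariates + λ6·sleep_i,j−1`

λ₁ — the log-odds ratio per unit of lagged exposure (true OR 1.1 or 1.5)
— is the estimand.  The target analysis is a GEE with logit link,
unstructured working correlation and robust SEs on the wave 2–5 long
table; MI estimates are pooled by Rubin's rules.  Missingness is imposed
only on `bmiz` at waves 2–5, as monotone dropout plus intermittent holes,
either MCAR or MAR driven by the outcome at waves 1 and 5 and by maternal
smoking (an auxiliary variable available to the imputation models).
Methods are scored across replicates on bias, relative bias, empirical and
model-based SE, 95% coverage, RMSE and Monte-Carlo error.

See `docs/methods.md` for every modeling choice, default and limitation.

## Worked example

```python
from longmi import (default_dgm_params, generate_cohort, ImputationConfig,
                    impute, pool_completed, complete_case_estimate)
from longmi.missingness import MissingnessSpec, apply_missingness

dgm = default_dgm_params(true_or=1.1)          # true log-OR 0.0953
panel = generate_cohort(5000, dgm, seed=4)
pattern = apply_missingness(panel, MissingnessSpec("MAR_strong", 0.5), seed=5)
masked = pattern.mask(panel)

cca = complete_case_estimate(masked)
pooled = pool_completed(impute(masked, "FCS",
                               ImputationConfig(m=20, da_burnin=100, da_thin=25, seed=6)))
print(cca.beta1, pooled.estimate)
```

Running `python examples/03_impute_and_pool.py` (which does the above for
all methods) prints:

```
true log-OR 0.0953
full data      estimate +0.0663  SE 0.0211
complete case  estimate +0.0525  SE 0.0318  (n = 2572 children retained)
FCS            estimate +0.0682  SE 0.0231  (within 4.54e-04, between 7.46e-05, df 878)
MVNI           estimate +0.0702  SE 0.0235  (within 4.54e-04, between 9.48e-05, df 588)
TWOFOLD_W1     estimate +0.0639  SE 0.0230  (within 4.54e-04, between 7.22e-05, df 927)
TWOFOLD_W2     estimate +0.0702  SE 0.0249  (within 4.55e-04, between 1.58e-04, df 267)
```

On this single cohort the MI estimates track the full-data estimate while
the complete-case estimate is pulled toward zero (half the children are
dropped, selectively by outcome) and loses precision.  Across many
replicates this becomes the headline pattern: MI bias ≈ 0 with ~95%
coverage; CCA bias grows with the strength of the MAR mechanism.

The other scripts in `examples/` walk through cohort generation,
missingness imposition and a small replicate study; each prints what its
numbers mean.  A thin CLI wraps the same calls
(`longmi simulate | impose | impute | analyze | study`), e.g.

```bash
longmi study --n 1000 --replicates 20 --true-ors 1.1 --mechanisms MAR_strong \
             --proportions 0.5 --methods CCA,FCS --m 5 --seed 7 --out-dir out/
```

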