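"""Impute one masked cohort with all three MI methods and pool by Rubin's rules.

Compares the pooled lagged-exposure log-OR from FCS, MVNI and two-fold FCS
(widths 1 and 2) against the complete-case estimate and the estimate from
the original complete data, on a single 5000-child cohort with 50% strong
MAR missingness.
"""

import numpy as np

from longmi import (
    ImputationConfig,
    build_analysis_long,
    complete_case_estimate,
    default_dgm_params,
    fit_gee,
    generate_cohort,
    impute,
    pool_completed,
)
from longmi.missingness import MissingnessSpec, apply_missingness

dgm = default_dgm_params(1.1)
true = dgm.true_log_or
panel = generate_cohort(5000, dgm, seed=4)
pattern = apply_missingness(panel, MissingnessSpec(mechanism="MAR_strong", target_final=0.5), seed=5)
masked = pattern.mask(panel)

full = fit_gee(build_analysis_long(panel))
print(f"true log-OR {true:.4f}")
print(f"{'full data':14s} estimate {full.beta1:+.4f}  SE {full.se:.4f}")

cca = complete_case_estimate(masked)
print(f"{'complete case':14s} estimate {cca.beta1:+.4f}  SE {cca.se:.4f}  "
      f"(n = {cca.n_clusters} children retained)")

config = ImputationConfig(m=20, da_burnin=100, da_thin=25, seed=6)
for method in ("FCS", "MVNI", "TWOFOLD_W1", "TWOFOLD_W2"):
    pooled = pool_completed(impute(masked, method, config))
    print(f"{method:14s} estimate {pooled.estimate:+.4f}  SE {pooled.se:.4f}  "
          f"(within {pooled.W:.2e}, between {pooled.B:.2e}, df {pooled.df:.0f})")

print("\nMI estimates sit near the full-data value while the complete-case"
      "\nestimate is pulled toward zero: missingness depends on the outcome,"
      "\nso dropping incomplete children distorts the exposure-outcome link.")
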