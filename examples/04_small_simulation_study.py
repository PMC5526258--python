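"""Run a small replicate study and read the performance table.

Twenty replicates of 1000 children under strong MAR at 50% missingness,
comparing complete-case analysis with FCS: the summary reports the seven
metrics computed across replicates.  At full scale the study uses 1000
replicates of 5000 children and all five methods.
"""

from longmi import ImputationConfig, StudyConfig
from longmi.study import run_scenario

config = StudyConfig(
    n_individuals=1000,
    n_replicates=20,
    mechanisms=("MAR_strong",),
    proportions=(0.5,),
    methods=("CCA", "FCS"),
    imputation=ImputationConfig(m=5, da_burnin=60, da_thin=15),
    master_seed=7,
)
summary, replicates = run_scenario(config, "MAR_strong", 0.5, 1.1)

cols = ["method", "absolute_bias", "relative_bias_pct", "empirical_se",
        "model_based_se", "coverage_pct", "rmse", "mc_error"]
print(summary[cols].round(4).to_string(index=False))

print("\nabsolute_bias: |mean estimate - true log-OR| across replicates;"
      "\ncoverage_pct: percent of replicate 95% CIs containing the truth;"
      "\nrmse combines bias and empirical SE.  CCA shows the larger bias"
      "\nunder this outcome-dependent mechanism; note the mc_error column -"
      "\nat 20 replicates the Monte-Carlo noise is still substantial, which"
      "\nis why the full design uses 1000 replicates.")
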