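"""Performance measures for a scenario x method cell of the simulation study.

Given the per-replicate estimates, standard errors and confidence intervals
of one method under one scenario, computes the seven standard simulation
metrics: absolute bias, relative bias (%), empirical SE, model-based SE,
coverage (%), RMSE and the Monte Carlo error of the mean estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScenarioResult", "PerformanceSummary", "summarize"]


@dataclass
class ScenarioResult:
    """Replicate-level estimates for one scenario x method cell."""

    true_log_or: float
    estimates: np.ndarray
    ses: np.ndarray
    ci_lows: np.ndarray
    ci_highs: np.ndarray

    def __post_init__(self):
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.ci_lows = np.asarray(self.ci_lows, dtype=float)
        self.ci_highs = np.asarray(self.ci_highs, dtype=float)
        n = len(self.estimates)
        if n < 2:
            raise ValueError("need at least 2 replicates")
        for arr in (self.ses, self.ci_lows, self.ci_highs):
            if len(arr) != n:
                raise ValueError("replicate arrays must have equal length")
        if not np.all(np.isfinite(self.estimates)):
            raise ValueError("estimates must be finite")

    @property
    def n_replicates(self) -> int:
        return len(self.estimates)


@dataclass
class PerformanceSummary:
    """The seven scenario metrics (bias reported as a magnitude)."""

    absolute_bias: float
    relative_bias_pct: float
    empirical_se: float
    model_based_se: float
    coverage_pct: float
    rmse: float
    mc_error: float
    signed_bias: float  # kept for diagnostics; the headline bias is |.|
    n_replicates: int


def summarize(result: ScenarioResult) -> PerformanceSummary:
    """Compute the seven metrics across replicates.

    * bias = |mean(estimate) - true|; relative bias = 100 bias / |true|
    * empirical SE = SD of estimates (ddof 1); model-based SE = mean SE
    * coverage = % of replicates whose 95% CI contains the true value
    * RMSE = sqrt(bias^2 + empirical SE^2), so the bias/variance identity
      holds exactly by construction
    * MC error = empirical SE / sqrt(R), the simulation noise on the mean
    """
    true = result.true_log_or
    est = result.estimates
    signed = float(est.mean() - true)
    bias = abs(signed)
    emp_se = float(est.std(ddof=1))
    covered = (result.ci_lows <= true) & (true <= result.ci_highs)
    return PerformanceSummary(
        absolute_bias=bias,
        relative_bias_pct=100.0 * bias / abs(true),
        empirical_se=emp_se,
        model_based_se=float(result.ses.mean()),
        coverage_pct=100.0 * float(covered.mean()),
        rmse=float(np.sqrt(bias**2 + emp_se**2)),
        mc_error=emp_se / np.sqrt(result.n_replicates),
        signed_bias=signed,
        n_replicates=result.n_replicates,
    )
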