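"""Scenario-grid orchestration for the simulation study.

A *scenario* is (missingness mechanism, final missing proportion, true odds
ratio); for each scenario every requested method is evaluated on the same
stream of replicates: generate a complete cohort, impose missingness, then
estimate the lagged-exposure log-odds ratio by complete-case GEE or by an
MI method with Rubin pooling.  Replicate seeds are derived from the master
seed and the scenario identity alone, so method comparisons are paired on
identical incomplete datasets and enabling or disabling methods never
changes the data a method sees.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import complete_case_estimate, pool_completed
from .cohort import default_dgm_params, generate_cohort
from .impute import ImputationConfig, impute
from .missingness import MAR_STRONG, MAR_WEAK, MCAR, MissingnessSpec, apply_missingness
from .performance import ScenarioResult, summarize

__all__ = ["StudyConfig", "run_scenario", "run_study", "write_results", "ALL_METHODS"]

ALL_METHODS = ("CCA", "FCS", "MVNI", "TWOFOLD_W1", "TWOFOLD_W2")
_MECHANISMS = (MCAR, MAR_WEAK, MAR_STRONG)

METRIC_COLS = [
    "absolute_bias",
    "relative_bias_pct",
    "empirical_se",
    "model_based_se",
    "coverage_pct",
    "rmse",
    "mc_error",
]


@dataclass(frozen=True)
class StudyConfig:
    """Full description of a study run (defaults mirror the full design)."""

    n_individuals: int = 5000
    n_replicates: int = 1000
    true_ors: tuple[float, ...] = (1.1, 1.5)
    mechanisms: tuple[str, ...] = _MECHANISMS
    proportions: tuple[float, ...] = (0.25, 0.50)
    methods: tuple[str, ...] = ALL_METHODS
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        unknown = set(m.upper() for m in self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not (self.true_ors and self.mechanisms and self.proportions and self.methods):
            raise ValueError("scenario grid must be non-empty")


def replicate_seed(master_seed: int, mechanism: str, proportion: float, true_or: float, r: int) -> np.random.SeedSequence:
    """Deterministic replicate seed, independent of the enabled methods."""
    mech_idx = _MECHANISMS.index(mechanism)
    key = (master_seed, mech_idx, int(round(proportion * 10_000)), int(round(true_or * 1_000)), r)
    return np.random.SeedSequence(key)


def run_scenario(
    config: StudyConfig, mechanism: str, proportion: float, true_or: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every enabled method over the scenario's replicates.

    Returns ``(summaries, replicates)``: one metrics row per method, and
    the per-replicate estimates persisted for audit.  Replicates where a
    method fails (non-convergence, no complete cases) are excluded from
    that method's summary and counted in ``n_failed``.
    """
    dgm = default_dgm_params(true_or)
    true_log_or = dgm.true_log_or
    methods = tuple(m.upper() for m in config.methods)
    records: list[dict] = []
    for r in range(config.n_replicates):
        ss = replicate_seed(config.master_seed, mechanism, proportion, true_or, r)
        s_cohort, s_miss, s_imp = ss.spawn(3)
        panel = generate_cohort(config.n_individuals, dgm, s_cohort)
        spec = MissingnessSpec(mechanism=mechanism, target_final=proportion)
        pattern = apply_missingness(panel, spec, np.random.default_rng(s_miss))
        masked = pattern.mask(panel)
        imp_seed = int(s_imp.generate_state(1)[0] % (2**31))
        for method in methods:
            rec = {"replicate": r, "method": method, "failed": False}
            try:
                if method == "CCA":
                    est = complete_case_estimate(masked)
                    if not est.converged:
                        raise RuntimeError("GEE did not converge")
                    rec.update(
                        estimate=est.beta1, se=est.se, ci_low=est.ci_low, ci_high=est.ci_high
                    )
                else:
                    imp_cfg = replace(config.imputation, seed=imp_seed)
                    pooled = pool_completed(impute(masked, method, imp_cfg))
                    rec.update(
                        estimate=pooled.estimate,
                        se=pooled.se,
                        ci_low=pooled.ci_low,
                        ci_high=pooled.ci_high,
                    )
            except (RuntimeError, ValueError):
                rec["failed"] = True
            records.append(rec)
    reps = pd.DataFrame.from_records(records)
    reps.insert(0, "true_or", true_or)
    reps.insert(0, "proportion", proportion)
    reps.insert(0, "mechanism", mechanism)

    rows = []
    for method in methods:
        sub = reps[(reps["method"] == method) & (~reps["failed"])]
        n_failed = int((reps["method"] == method).sum() - len(sub))
        row = {
            "mechanism": mechanism,
            "proportion": proportion,
            "true_or": true_or,
            "true_log_or": true_log_or,
            "method": method,
            "n_replicates": len(sub),
            "n_failed": n_failed,
        }
        if len(sub) >= 2:
            summary = summarize(
                ScenarioResult(
                    true_log_or=true_log_or,
                    estimates=sub["estimate"].to_numpy(),
                    ses=sub["se"].to_numpy(),
                    ci_lows=sub["ci_low"].to_numpy(),
                    ci_highs=sub["ci_high"].to_numpy(),
                )
            )
            row.update({k: getattr(summary, k) for k in METRIC_COLS + ["signed_bias"]})
        rows.append(row)
    return pd.DataFrame(rows), reps


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full scenario grid; returns (summary table, replicate table)."""
    summaries, replicates = [], []
    for true_or in config.true_ors:
        for mechanism in config.mechanisms:
            for proportion in config.proportions:
                summ, reps = run_scenario(config, mechanism, proportion, true_or)
                summaries.append(summ)
                replicates.append(reps)
    summary = pd.concat(summaries, ignore_index=True)
    reps = pd.concat(replicates, ignore_index=True)
    if config.out_dir is not None:
        write_results(summary, reps, config)
    return summary, reps


def write_results(summary: pd.DataFrame, replicates: pd.DataFrame, config: StudyConfig) -> dict:
    """Write the tidy summary CSV, replicate CSV and a JSON run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)
    replicates.to_csv(out / "replicates.csv", index=False)
    manifest = {
        "package": "longmi",
        "version": __version__,
        "master_seed": config.master_seed,
        "config": _jsonable(asdict(config)),
        "n_summary_rows": int(len(summary)),
        "n_failed_total": int(summary.get("n_failed", pd.Series(dtype=int)).sum()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def table_wide(summary: pd.DataFrame, mechanism_order=_MECHANISMS) -> pd.DataFrame:
    """Pivot the tidy summary into the familiar wide report layout:
    one block of metric rows per mechanism, one column per method."""
    blocks = []
    for mech in mechanism_order:
        sub = summary[summary["mechanism"] == mech]
        if sub.empty:
            continue
        block = sub.set_index("method")[METRIC_COLS].T
        block.insert(0, "mechanism", mech)
        blocks.append(block)
    return pd.concat(blocks)
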