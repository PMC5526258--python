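"""Impose MCAR or MAR missingness on the exposure at waves 2-5.

Missingness is generated wave by wave from two logistic models: model A
produces *dropout* (once missing, missing at every later wave) and model B
produces *intermittent* missingness (a single wave), applied only to
children not already lost to dropout.  Under MAR the log-odds depend on the
outcome at waves 1 and 5 and on maternal smoking; under MCAR both models are
intercept-only.  Model intercepts are calibrated per dataset by monotone
root-finding so the expected cumulative missing fraction at each wave hits
its target; wave-1 exposure is never masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import N_WAVES

__all__ = [
    "MCAR",
    "MAR_WEAK",
    "MAR_STRONG",
    "MarModelParams",
    "MAR_WEAK_PARAMS",
    "MAR_STRONG_PARAMS",
    "MissingnessSpec",
    "MissingnessPattern",
    "calibrate_intercept",
    "apply_missingness",
    "apply_mar",
    "apply_mcar",
    "missing_fraction",
]

MCAR = "MCAR"
MAR_WEAK = "MAR_weak"
MAR_STRONG = "MAR_strong"


@dataclass(frozen=True)
class MarModelParams:
    """Log-odds ratios of the two missingness models.

    Order of effects in each triple: sleep problem at wave 1, sleep problem
    at wave 5, maternal smoking.  ``dropout`` parameterizes model A,
    ``intermittent`` model B.
    """

    dropout: tuple[float, float, float]
    intermittent: tuple[float, float, float]


def _log(ors):
    return tuple(float(np.log(v)) for v in ors)


# Published odds ratios for the weak and strong MAR scenarios; the strong
# values are the squares of the weak ones after 2-decimal rounding.
MAR_WEAK_PARAMS = MarModelParams(
    dropout=_log((1.67, 1.64, 1.61)), intermittent=_log((1.61, 1.58, 1.58))
)
MAR_STRONG_PARAMS = MarModelParams(
    dropout=_log((2.80, 2.70, 2.60)), intermittent=_log((2.60, 2.50, 2.50))
)

_MECHANISM_PARAMS = {
    MCAR: MarModelParams(dropout=(0.0, 0.0, 0.0), intermittent=(0.0, 0.0, 0.0)),
    MAR_WEAK: MAR_WEAK_PARAMS,
    MAR_STRONG: MAR_STRONG_PARAMS,
}


def _linear_ramp(target_final: float) -> tuple[float, float, float, float]:
    return tuple(target_final * k / 4.0 for k in (1, 2, 3, 4))


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism, per-wave cumulative targets and the dropout/intermittent split.

    ``per_wave_targets`` are cumulative missing proportions for waves 2..5;
    by default they grow linearly to ``target_final`` at wave 5.
    ``dropout_share`` is the fraction of each wave's cumulative target
    attributed to model A.
    """

    mechanism: str = MCAR
    target_final: float = 0.25
    per_wave_targets: tuple[float, float, float, float] | None = None
    dropout_share: float = 0.5
    mar_params: MarModelParams | None = None

    def __post_init__(self):
        if self.mechanism not in _MECHANISM_PARAMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.target_final < 1.0:
            raise ValueError("target_final must be in [0, 1)")
        targets = self.per_wave_targets
        if targets is None:
            object.__setattr__(self, "per_wave_targets", _linear_ramp(self.target_final))
        else:
            targets = tuple(float(t) for t in targets)
            if len(targets) != 4 or any(np.diff(targets) < 0):
                raise ValueError("per_wave_targets must be 4 non-decreasing proportions")
            if abs(targets[-1] - self.target_final) > 1e-12:
                raise ValueError("per_wave_targets[-1] must equal target_final")
            object.__setattr__(self, "per_wave_targets", targets)
        if self.mar_params is None:
            object.__setattr__(self, "mar_params", _MECHANISM_PARAMS[self.mechanism])


@dataclass
class MissingnessPattern:
    """Realized missingness indicators for waves 2..5.

    ``R[i, j]`` is 1 when the exposure of child ``i`` at wave ``j + 2`` is
    missing.  ``dropout_wave`` is the first all-subsequent-missing wave per
    child (0 = never).  Calibrated intercepts are kept for audit.
    """

    R: np.ndarray
    dropout_wave: np.ndarray
    intercepts: dict = field(default_factory=dict)

    def mask(self, panel: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of ``panel`` with masked exposure cells set to NaN."""
        out = panel.copy()
        for j in range(2, N_WAVES + 1):
            col = out[f"bmiz{j}"].to_numpy(dtype=float, copy=True)
            col[self.R[:, j - 2].astype(bool)] = np.nan
            out[f"bmiz{j}"] = col
        return out


def calibrate_intercept(linear_predictor: np.ndarray, target: float) -> float:
    """Intercept c such that ``mean(expit(c + linear_predictor)) == target``.

    Monotone root-finding on the expected proportion; accurate to 1e-6 or
    better.  ``target`` must lie strictly inside (0, 1).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    lo, hi = -40.0, 40.0
    return float(brentq(lambda c: expit(c + lp).mean() - target, lo, hi, xtol=1e-9))


def _mar_linpred(panel: pd.DataFrame, coef: tuple[float, float, float]) -> np.ndarray:
    return (
        coef[0] * panel["sleep_prob1"].to_numpy(dtype=float)
        + coef[1] * panel["sleep_prob5"].to_numpy(dtype=float)
        + coef[2] * panel["m_smoking"].to_numpy(dtype=float)
    )


def apply_missingness(
    panel: pd.DataFrame, spec: MissingnessSpec, seed
) -> MissingnessPattern:
    """Generate a missingness pattern for the exposure at waves 2-5.

    At each wave transition, model A first recruits new dropouts among
    children not yet dropped out, then model B marks intermittent
    missingness among the remaining non-dropouts; intercepts are solved so
    the expected cumulative missing fraction matches the spec's target for
    that wave, given the realized state of earlier waves.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(panel)
    lp_a = _mar_linpred(panel, spec.mar_params.dropout)
    lp_b = _mar_linpred(panel, spec.mar_params.intermittent)

    R = np.zeros((n, 4), dtype=np.int8)
    dropout = np.zeros(n, dtype=bool)
    dropout_wave = np.zeros(n, dtype=np.int8)
    intercepts: dict = {"nu0": {}, "omega0": {}}

    for wave in range(2, N_WAVES + 1):
        c_target = spec.per_wave_targets[wave - 2]
        # model A: new dropout, aiming the cumulative dropout mass at
        # dropout_share * cumulative target
        target_dropout = spec.dropout_share * c_target
        eligible = ~dropout
        new_mass = target_dropout * n - dropout.sum()
        if new_mass > 0.5 and eligible.any():
            prop = min(new_mass / eligible.sum(), 1.0 - 1e-9)
            nu0 = calibrate_intercept(lp_a[eligible], prop)
            intercepts["nu0"][wave] = nu0
            hit = rng.random(eligible.sum()) < expit(nu0 + lp_a[eligible])
            idx = np.flatnonzero(eligible)[hit]
            dropout[idx] = True
            dropout_wave[idx] = wave
        # model B: intermittent missingness among current non-dropouts,
        # filling the gap between realized dropout and the cumulative target
        eligible_b = ~dropout
        b_mass = c_target * n - dropout.sum()
        wave_missing = dropout.copy()
        if b_mass > 0.5 and eligible_b.any():
            prop = min(b_mass / eligible_b.sum(), 1.0 - 1e-9)
            omega0 = calibrate_intercept(lp_b[eligible_b], prop)
            intercepts["omega0"][wave] = omega0
            hit = rng.random(eligible_b.sum()) < expit(omega0 + lp_b[eligible_b])
            wave_missing[np.flatnonzero(eligible_b)[hit]] = True
        R[:, wave - 2] = wave_missing

    return MissingnessPattern(R=R, dropout_wave=dropout_wave, intercepts=intercepts)


def apply_mar(panel: pd.DataFrame, spec: MissingnessSpec, seed) -> MissingnessPattern:
    """MAR missingness; requires a MAR mechanism in the spec."""
    if spec.mechanism not in (MAR_WEAK, MAR_STRONG):
        raise ValueError("apply_mar requires a MAR mechanism")
    return apply_missingness(panel, spec, seed)


def apply_mcar(panel: pd.DataFrame, spec: MissingnessSpec, seed) -> MissingnessPattern:
    """MCAR missingness (intercept-only models); same two-pattern machinery."""
    if spec.mechanism != MCAR:
        raise ValueError("apply_mcar requires the MCAR mechanism")
    return apply_missingness(panel, spec, seed)


def missing_fraction(pattern: MissingnessPattern, wave: int) -> float:
    """Fraction of children with a missing exposure at ``wave`` (2..5)."""
    if not 2 <= wave <= N_WAVES:
        raise ValueError("wave must be in 2..5")
    return float(pattern.R[:, wave - 2].mean())
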