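"""Synthetic longitudinal cohort generator.

Emulates a five-wave child cohort in which a continuous exposure (BMI-for-age
z-score, ``bmiz``) follows a quadratic-in-age trajectory with person-level
random intercept and slopes, and a repeated binary outcome (sleep problems)
depends on the exposure at the previous wave.  The generating models are

* wave-1 outcome: logistic in maternal education, sex, birthweight and
  maternal age;
* exposure, waves 1-5: linear mixed model in wave-1 outcome, age (months),
  age squared and the time-invariant covariates, with random intercept and
  random linear/quadratic age slopes;
* outcome, waves 2-5: logistic in the previous wave's exposure, the
  time-invariant covariates and the previous wave's outcome, generated
  sequentially so that the exposure log-odds ratio is the estimand of the
  downstream GEE target analysis.

Maternal smoking influences the exposure but not the outcome directly; it is
the auxiliary variable used later by the imputation models.

Panels are plain :class:`pandas.DataFrame` objects in wide layout, one row
per child, with columns ``sex, birthweight, m_age, m_education, m_smoking``
and ``scage{j}, bmiz{j}, sleep_prob{j}`` for waves ``j = 1..5``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "N_WAVES",
    "TimeInvariantParams",
    "AgeParams",
    "Wave1SleepParams",
    "BmizTrajectoryParams",
    "SleepFollowupParams",
    "DGMParams",
    "sample_time_invariant",
    "sample_ages",
    "sample_wave1_sleep",
    "sample_bmiz_trajectory",
    "sample_sleep_followup",
    "generate_cohort",
    "calibrate_dgm",
    "default_dgm_params",
    "panel_columns",
]

N_WAVES = 5

TIME_INVARIANT_COLS = ["sex", "birthweight", "m_age", "m_education", "m_smoking"]


def panel_columns() -> list[str]:
    """Column names of a complete wide panel, in canonical order."""
    cols = list(TIME_INVARIANT_COLS)
    for stem in ("scage", "scage_sq", "bmiz", "sleep_prob"):
        cols += [f"{stem}{j}" for j in range(1, N_WAVES + 1)]
    return cols


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeInvariantParams:
    """Distributions of the five time-invariant covariates.

    The dependency chain is: sex and maternal age are exogenous; birthweight
    depends on sex; maternal education depends on maternal age; maternal
    smoking depends on maternal education.  All values are configuration
    choices representing a plausible Australian birth cohort, not estimates.
    """

    p_female: float = 0.49
    m_age_mean: float = 31.0
    m_age_sd: float = 5.0
    m_age_bounds: tuple[float, float] = (18.0, 45.0)
    bw_base: float = 3.30          # kg, mean for girls
    bw_male_shift: float = 0.12    # boys heavier on average
    bw_sd: float = 0.55
    bw_bounds: tuple[float, float] = (1.0, 6.0)
    edu_intercept: float = -0.6
    edu_per_year: float = 0.05     # log-odds per year of maternal age above the mean
    smoke_intercept: float = -1.0
    smoke_edu_effect: float = -0.9


@dataclass(frozen=True)
class AgeParams:
    """Child age at each wave: ~4.75 y at wave 1, then two-yearly waves."""

    wave1_mean: float = 57.0       # months
    wave1_sd: float = 3.0
    wave1_bounds: tuple[float, float] = (48.0, 72.0)
    gap_mean: float = 24.0         # months between waves
    gap_sd: float = 1.0


@dataclass(frozen=True)
class Wave1SleepParams:
    """Log-odds coefficients of the wave-1 sleep-problem model."""

    eta0: float = 0.0              # intercept; calibrated to the target prevalence
    eta1: float = -0.25            # maternal education completed
    eta2: float = 0.10             # female
    eta3: float = -0.15            # birthweight (per kg)
    eta4: float = -0.01            # maternal age (per year)


@dataclass(frozen=True)
class BmizTrajectoryParams:
    """Fixed effects, random-effect law and residual SD of the bmiz model.

    theta = (intercept, wave-1 sleep, age, age^2, m_education, m_smoking,
    sex, birthweight, m_age); random effects (a0, a1, a2) act on the
    intercept, age and age^2 terms and are multivariate normal.
    """

    theta: tuple[float, ...] = (
        0.0,        # theta0 intercept; calibrated to the target wave-1 mean
        0.10,       # theta1 wave-1 sleep problem
        0.015,      # theta2 per month of age
        -5e-5,      # theta3 per month^2 (concave trajectory)
        -0.10,      # theta4 maternal education
        0.15,       # theta5 maternal smoking
        -0.05,      # theta6 female
        0.40,       # theta7 birthweight (per kg)
        -0.005,     # theta8 maternal age (per year)
    )
    sigma_eps: float = 0.45
    mu_a: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma_a: tuple[tuple[float, ...], ...] = (
        (0.85**2, -0.3 * 0.85 * 0.004, 0.0),
        (-0.3 * 0.85 * 0.004, 0.004**2, 0.0),
        (0.0, 0.0, 1e-5**2),
    )

    def sigma_a_matrix(self) -> np.ndarray:
        return np.asarray(self.sigma_a, dtype=float)


@dataclass(frozen=True)
class SleepFollowupParams:
    """Log-odds coefficients of the waves 2-5 sleep-problem model.

    ``lam1`` (the lagged-exposure effect) is the true value of the parameter
    the whole study estimates.
    """

    lam0: float = 0.0              # intercept; calibrated to the target prevalence
    lam1: float = float(np.log(1.1))
    lam2: float = -0.20            # maternal education
    lam3: float = 0.10             # female
    lam4: float = -0.10            # birthweight
    lam5: float = -0.01            # maternal age
    lam6: float = 1.2              # previous-wave sleep problem


@dataclass(frozen=True)
class DGMParams:
    """Bundle of every data-generating-model parameter."""

    time_invariant: TimeInvariantParams = field(default_factory=TimeInvariantParams)
    ages: AgeParams = field(default_factory=AgeParams)
    wave1_sleep: Wave1SleepParams = field(default_factory=Wave1SleepParams)
    bmiz: BmizTrajectoryParams = field(default_factory=BmizTrajectoryParams)
    followup: SleepFollowupParams = field(default_factory=SleepFollowupParams)

    @property
    def true_log_or(self) -> float:
        return self.followup.lam1


# --------------------------------------------------------------------------
# sampling operations
# --------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncnorm(rng, mean, sd, bounds, size):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_time_invariant(
    n: int, seed, params: TimeInvariantParams | None = None
) -> pd.DataFrame:
    """Draw ``n`` time-invariant covariate profiles.

    Returns a DataFrame with columns sex, birthweight, m_age, m_education,
    m_smoking.  Reproducible given the seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = params or TimeInvariantParams()
    rng = _as_rng(seed)
    sex = (rng.random(n) < p.p_female).astype(np.int8)
    m_age = _truncnorm(rng, p.m_age_mean, p.m_age_sd, p.m_age_bounds, n)
    bw_mean = p.bw_base + p.bw_male_shift * (1 - sex)
    a = (p.bw_bounds[0] - bw_mean) / p.bw_sd
    b = (p.bw_bounds[1] - bw_mean) / p.bw_sd
    birthweight = truncnorm.rvs(a, b, loc=bw_mean, scale=p.bw_sd, random_state=rng)
    p_edu = expit(p.edu_intercept + p.edu_per_year * (m_age - p.m_age_mean))
    m_education = (rng.random(n) < p_edu).astype(np.int8)
    p_smoke = expit(p.smoke_intercept + p.smoke_edu_effect * m_education)
    m_smoking = (rng.random(n) < p_smoke).astype(np.int8)
    return pd.DataFrame(
        {
            "sex": sex,
            "birthweight": birthweight,
            "m_age": m_age,
            "m_education": m_education,
            "m_smoking": m_smoking,
        }
    )


def sample_ages(n: int, seed, params: AgeParams | None = None) -> np.ndarray:
    """Draw an (n, 5) matrix of ages in months, strictly increasing per row."""
    p = params or AgeParams()
    rng = _as_rng(seed)
    ages = np.empty((n, N_WAVES))
    ages[:, 0] = _truncnorm(rng, p.wave1_mean, p.wave1_sd, p.wave1_bounds, n)
    for j in range(1, N_WAVES):
        ages[:, j] = ages[:, j - 1] + p.gap_mean + rng.normal(0.0, p.gap_sd, n)
    return ages


def _wave1_linpred_no_intercept(profiles: pd.DataFrame, p: Wave1SleepParams) -> np.ndarray:
    return (
        p.eta1 * profiles["m_education"].to_numpy()
        + p.eta2 * profiles["sex"].to_numpy()
        + p.eta3 * profiles["birthweight"].to_numpy()
        + p.eta4 * profiles["m_age"].to_numpy()
    )


def sample_wave1_sleep(
    profiles: pd.DataFrame, params: Wave1SleepParams, seed
) -> np.ndarray:
    """Bernoulli wave-1 sleep-problem indicators from the logistic model."""
    rng = _as_rng(seed)
    prob = expit(params.eta0 + _wave1_linpred_no_intercept(profiles, params))
    return (rng.random(len(profiles)) < prob).astype(np.int8)


def _bmiz_fixed_part(
    profiles: pd.DataFrame,
    wave1_sleep: np.ndarray,
    ages: np.ndarray,
    p: BmizTrajectoryParams,
) -> np.ndarray:
    th = p.theta
    person = (
        th[0]
        + th[1] * np.asarray(wave1_sleep, dtype=float)
        + th[4] * profiles["m_education"].to_numpy()
        + th[5] * profiles["m_smoking"].to_numpy()
        + th[6] * profiles["sex"].to_numpy()
        + th[7] * profiles["birthweight"].to_numpy()
        + th[8] * profiles["m_age"].to_numpy()
    )
    return person[:, None] + th[2] * ages + th[3] * ages**2


def sample_bmiz_trajectory(
    profiles: pd.DataFrame,
    wave1_sleep: np.ndarray,
    ages: np.ndarray,
    params: BmizTrajectoryParams,
    seed,
) -> np.ndarray:
    """Draw the (n, 5) exposure matrix from the linear mixed model.

    Each child's trajectory is the population quadratic in age plus a
    person-specific random intercept and random linear/quadratic age slopes,
    plus iid residual noise.
    """
    n = len(profiles)
    if ages.shape != (n, N_WAVES):
        raise ValueError("ages must be n x 5")
    if np.any(np.diff(ages, axis=1) <= 0):
        raise ValueError("ages must be strictly increasing within each row")
    sigma = params.sigma_a_matrix()
    if sigma.shape != (3, 3) or not np.allclose(sigma, sigma.T):
        raise ValueError("Sigma_a must be symmetric 3x3")
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() < -1e-10 * max(1.0, eig.max()):
        raise ValueError("Sigma_a must be positive semi-definite")
    rng = _as_rng(seed)
    a = rng.multivariate_normal(np.asarray(params.mu_a), sigma, size=n, method="eigh")
    random_part = a[:, [0]] + a[:, [1]] * ages + a[:, [2]] * ages**2
    eps = rng.normal(0.0, params.sigma_eps, size=(n, N_WAVES))
    return _bmiz_fixed_part(profiles, wave1_sleep, ages, params) + random_part + eps


def _followup_linpred_no_intercept_no_lag(
    profiles: pd.DataFrame, p: SleepFollowupParams
) -> np.ndarray:
    return (
        p.lam2 * profiles["m_education"].to_numpy()
        + p.lam3 * profiles["sex"].to_numpy()
        + p.lam4 * profiles["birthweight"].to_numpy()
        + p.lam5 * profiles["m_age"].to_numpy()
    )


def sample_sleep_followup(
    profiles: pd.DataFrame,
    bmiz: np.ndarray,
    wave1_sleep: np.ndarray,
    params: SleepFollowupParams,
    seed,
) -> np.ndarray:
    """Sequentially draw sleep-problem indicators for waves 2-5.

    The wave-j indicator is Bernoulli with logit equal to
    ``lam0 + lam1 * bmiz_{j-1} + covariates + lam6 * sleep_{j-1}``.
    Returns an (n, 4) int matrix for waves 2..5.
    """
    n = len(profiles)
    bmiz = np.asarray(bmiz, dtype=float)
    if bmiz.shape != (n, N_WAVES) or np.isnan(bmiz[:, : N_WAVES - 1]).any():
        raise ValueError("bmiz waves 1..4 must be present for every child")
    rng = _as_rng(seed)
    base = _followup_linpred_no_intercept_no_lag(profiles, params)
    out = np.empty((n, N_WAVES - 1), dtype=np.int8)
    prev = np.asarray(wave1_sleep, dtype=float)
    for j in range(2, N_WAVES + 1):
        eta = params.lam0 + params.lam1 * bmiz[:, j - 2] + base + params.lam6 * prev
        draw = (rng.random(n) < expit(eta)).astype(np.int8)
        out[:, j - 2] = draw
        prev = draw.astype(float)
    return out


def generate_cohort(n: int, dgm: DGMParams, seed: int) -> pd.DataFrame:
    """Generate a complete wide panel of ``n`` children.

    Composes the four sampling stages (time-invariant covariates and ages,
    wave-1 outcome, exposure trajectory, follow-up outcomes) on
    deterministic per-stage substreams of ``seed``; identical arguments give
    bit-identical panels.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(5)]
    profiles = sample_time_invariant(n, streams[0], dgm.time_invariant)
    ages = sample_ages(n, streams[1], dgm.ages)
    sleep1 = sample_wave1_sleep(profiles, dgm.wave1_sleep, streams[2])
    bmiz = sample_bmiz_trajectory(profiles, sleep1, ages, dgm.bmiz, streams[3])
    sleep_rest = sample_sleep_followup(profiles, bmiz, sleep1, dgm.followup, streams[4])
    panel = profiles.copy()
    for j in range(N_WAVES):
        panel[f"scage{j + 1}"] = ages[:, j]
        panel[f"scage_sq{j + 1}"] = ages[:, j] ** 2
    for j in range(N_WAVES):
        panel[f"bmiz{j + 1}"] = bmiz[:, j]
    panel["sleep_prob1"] = sleep1
    for j in range(2, N_WAVES + 1):
        panel[f"sleep_prob{j}"] = sleep_rest[:, j - 2]
    return panel[panel_columns()]


# --------------------------------------------------------------------------
# intercept calibration
# --------------------------------------------------------------------------

_CALIBRATION_SEED = 202207  # fixed internal stream for the reference sample


def _solve_mean_expit(linpred: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + linpred)) == target, by root-finding."""
    lo, hi = -30.0, 30.0
    return float(brentq(lambda c: expit(c + linpred).mean() - target, lo, hi, xtol=1e-10))


def calibrate_dgm(
    dgm: DGMParams,
    wave1_prevalence: float = 0.15,
    wave1_bmiz_mean: float = 0.30,
    followup_prevalence: float = 0.15,
    n_ref: int = 100_000,
    seed: int = _CALIBRATION_SEED,
) -> DGMParams:
    """Fix the three model intercepts to hit the target marginals.

    Solves, on a large fixed reference sample of covariates and trajectories:

    * ``eta0`` so the expected wave-1 outcome prevalence equals
      ``wave1_prevalence``;
    * ``theta0`` so the expected wave-1 exposure mean equals
      ``wave1_bmiz_mean`` (closed form, the model being linear);
    * ``lam0`` so the expected outcome prevalence averaged over waves 2-5
      equals ``followup_prevalence`` at the scenario's ``lam1``, using an
      exact forward recursion over the previous-wave outcome distribution.

    Returns a new :class:`DGMParams`; the input is not modified.
    """
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)]
    profiles = sample_time_invariant(n_ref, streams[0], dgm.time_invariant)
    ages = sample_ages(n_ref, streams[1], dgm.ages)

    lp1 = _wave1_linpred_no_intercept(profiles, dgm.wave1_sleep)
    eta0 = _solve_mean_expit(lp1, wave1_prevalence)
    w1 = replace(dgm.wave1_sleep, eta0=eta0)
    p_sleep1 = expit(eta0 + lp1)

    # theta0: E[bmiz_1] is linear in theta0, so solve in closed form using the
    # expected wave-1 outcome probability in place of realized draws.
    bm = dgm.bmiz
    zero_int = replace(bm, theta=(0.0,) + bm.theta[1:])
    fixed_w1 = _bmiz_fixed_part(profiles, p_sleep1, ages, zero_int)[:, 0]
    theta0 = wave1_bmiz_mean - float(fixed_w1.mean())
    bmiz_params = replace(bm, theta=(theta0,) + bm.theta[1:])

    # lam0: simulate exposure trajectories once, then propagate the per-child
    # outcome probability exactly through waves 2..5 for each candidate lam0.
    sleep1_draw = (streams[2].random(n_ref) < p_sleep1).astype(np.int8)
    bmiz = sample_bmiz_trajectory(profiles, sleep1_draw, ages, bmiz_params, streams[2])
    base = _followup_linpred_no_intercept_no_lag(profiles, dgm.followup)
    lam1, lam6 = dgm.followup.lam1, dgm.followup.lam6

    def mean_prevalence(lam0: float) -> float:
        prev_p = p_sleep1.copy()
        total = 0.0
        for j in range(2, N_WAVES + 1):
            eta = lam0 + lam1 * bmiz[:, j - 2] + base
            pj = expit(eta + lam6) * prev_p + expit(eta) * (1.0 - prev_p)
            total += pj.mean()
            prev_p = pj
        return total / (N_WAVES - 1)

    lam0 = float(brentq(lambda c: mean_prevalence(c) - followup_prevalence, -30, 30, xtol=1e-10))
    followup = replace(dgm.followup, lam0=lam0)
    return replace(dgm, wave1_sleep=w1, bmiz=bmiz_params, followup=followup)


@lru_cache(maxsize=8)
def default_dgm_params(true_or: float = 1.1) -> DGMParams:
    """Calibrated default generating parameters for a scenario odds ratio.

    ``true_or`` is the odds ratio per unit of lagged exposure; the stored
    coefficient is its exact log (1.1 -> 0.0953..., 1.5 -> 0.4054...).
    """
    base = DGMParams(followup=SleepFollowupParams(lam1=float(np.log(true_or))))
    return calibrate_dgm(base)
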