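"""Multiple-imputation engines: FCS, MVNI and two-fold FCS.

All three methods are *proper*: each imputed value is a posterior-predictive
draw, so between-imputation variability reflects parameter uncertainty and
Rubin's rules apply downstream.

* FCS (chained equations) cycles univariate Bayesian linear regressions over
  the incomplete exposure waves, treating each wave's exposure and outcome
  as a distinct predictor column ("just another variable").
* MVNI fits a joint multivariate-normal model to all analysis and auxiliary
  variables by data augmentation (I-step: conditional-normal draws of the
  missing cells; P-step: normal-inverse-Wishart draw of mean and
  covariance), saving an imputation every ``da_thin`` iterations after
  burn-in.
* Two-fold FCS restricts each wave's imputation model to a time window of
  adjacent waves plus the time-invariant variables, iterating "among" time
  points with "within"-time refinement cycles.

Only the exposure at waves 2-5 is ever incomplete here, so every univariate
imputation model is linear-normal and the binary variables enter only as
complete predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import invwishart

from .cohort import N_WAVES, TIME_INVARIANT_COLS

__all__ = [
    "ImputationConfig",
    "CompletedSet",
    "DegenerateModelError",
    "bayesian_linear_draw",
    "fcs_impute",
    "mvni_impute",
    "twofold_fcs_impute",
    "twofold_predictor_waves",
    "impute",
]

BMIZ_COLS = [f"bmiz{j}" for j in range(1, N_WAVES + 1)]
SLEEP_COLS = [f"sleep_prob{j}" for j in range(1, N_WAVES + 1)]
MVN_COLS = BMIZ_COLS + SLEEP_COLS + TIME_INVARIANT_COLS


class DegenerateModelError(RuntimeError):
    """The imputation design is rank deficient beyond the ridge fallback."""


@dataclass(frozen=True)
class ImputationConfig:
    """Iteration counts and sizes shared by the MI engines.

    ``m`` completed datasets are produced.  ``fcs_cycles`` is the number of
    passes over the incomplete variables per FCS imputation; ``da_burnin``
    and ``da_thin`` control the MVNI data-augmentation chain;
    ``twofold_among``/``twofold_within`` are the two-fold iteration counts
    and ``window_width`` the half-width of its time window.
    """

    m: int = 50
    fcs_cycles: int = 10
    da_burnin: int = 200
    da_thin: int = 100
    twofold_among: int = 10
    twofold_within: int = 1
    window_width: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        for name in ("fcs_cycles", "da_burnin", "da_thin", "twofold_among", "twofold_within"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")


@dataclass
class CompletedSet:
    """``m`` completed copies of a panel, with provenance."""

    method: str
    panels: list[pd.DataFrame]
    seed: int
    width: int | None = None

    @property
    def m(self) -> int:
        return len(self.panels)


# --------------------------------------------------------------------------
# the proper-imputation primitive
# --------------------------------------------------------------------------


def bayesian_linear_draw(
    y_observed: np.ndarray,
    X_observed: np.ndarray,
    X_missing: np.ndarray,
    rng: np.random.Generator,
    column_names: list[str] | None = None,
) -> np.ndarray:
    """Posterior-predictive draw from a Bayesian linear regression.

    Under the standard noninformative prior, draws the residual variance
    from its scaled inverse-chi-square posterior, the coefficients from
    ``N(beta_hat, sigma*^2 (X'X)^-1)``, and returns
    ``X_missing @ beta* + N(0, sigma*^2)`` noise.  A tiny trace-scaled ridge
    stabilizes near-collinear designs; genuine rank deficiency raises
    :class:`DegenerateModelError`.
    """
    X_missing = np.asarray(X_missing, dtype=float)
    if X_missing.shape[0] == 0:
        return np.empty(0)
    y = np.asarray(y_observed, dtype=float)
    X = np.asarray(X_observed, dtype=float)
    n_obs, p = X.shape
    if n_obs <= p:
        raise DegenerateModelError(f"{n_obs} observed rows for {p} predictors")
    xtx = X.T @ X
    eigs = np.linalg.eigvalsh(xtx)
    if eigs[0] < 1e-10 * max(eigs[-1], 1e-300):
        bad = column_names if column_names else f"{p} columns"
        raise DegenerateModelError(f"rank-deficient imputation design ({bad})")
    ridge = 1e-8 * np.trace(xtx) / p
    xtx[np.diag_indices_from(xtx)] += ridge
    try:
        chol_lower, lower = cho_factor(xtx, lower=True)
    except np.linalg.LinAlgError as exc:
        bad = column_names if column_names else f"{p} columns"
        raise DegenerateModelError(f"rank-deficient design ({bad})") from exc
    beta_hat = cho_solve((chol_lower, lower), X.T @ y)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    dof = n_obs - p
    sigma2_star = rss / rng.chisquare(dof)
    # beta* = beta_hat + sigma* L^-T z with xtx = L L'
    z = rng.standard_normal(p)
    beta_star = beta_hat + np.sqrt(sigma2_star) * solve_triangular(chol_lower, z, lower=True, trans="T")
    return X_missing @ beta_star + rng.normal(0.0, np.sqrt(sigma2_star), X_missing.shape[0])


# --------------------------------------------------------------------------
# shared plumbing
# --------------------------------------------------------------------------


def _check_holes(panel: pd.DataFrame) -> dict[str, np.ndarray]:
    """Missing-row masks per incomplete column; holes allowed only in bmiz 2..5."""
    for col in panel.columns:
        vals = panel[col]
        if vals.isna().any() and col not in BMIZ_COLS[1:]:
            raise ValueError(f"missing values allowed only in bmiz waves 2..5, found in {col}")
    if panel["bmiz1"].isna().any():
        raise ValueError("wave-1 exposure must be complete")
    return {
        col: panel[col].isna().to_numpy()
        for col in BMIZ_COLS[1:]
        if panel[col].isna().any()
    }


def _init_from_margins(values: np.ndarray, miss: np.ndarray, rng) -> np.ndarray:
    """Fill holes with random draws (with replacement) from the observed margin."""
    out = values.copy()
    obs = values[~miss]
    out[miss] = rng.choice(obs, size=int(miss.sum()), replace=True)
    return out


def _imputation_rngs(config: ImputationConfig) -> list[np.random.Generator]:
    # independent substream per imputation: results do not depend on the
    # order in which imputations are produced
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(config.m)]


def _completed_panels(
    panel: pd.DataFrame, holes: dict[str, np.ndarray], fills: list[dict[str, np.ndarray]]
) -> list[pd.DataFrame]:
    out = []
    for fill in fills:
        copy = panel.copy()
        for col, miss in holes.items():
            vals = copy[col].to_numpy(dtype=float, copy=True)
            vals[miss] = fill[col]
            copy[col] = vals
        out.append(copy)
    return out


# --------------------------------------------------------------------------
# FCS
# --------------------------------------------------------------------------

FCS_STATIC_PREDICTORS = SLEEP_COLS + TIME_INVARIANT_COLS


def fcs_impute(panel: pd.DataFrame, config: ImputationConfig) -> CompletedSet:
    """Standard FCS treating each wave's exposure as a distinct variable.

    The model for each incomplete wave regresses it on the exposure at all
    other waves (current values), the outcome at all five waves, and the
    time-invariant covariates including the auxiliary maternal smoking.
    """
    holes = _check_holes(panel)
    static = panel[FCS_STATIC_PREDICTORS].to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(panel)), static])
    bmiz_true = {c: panel[c].to_numpy(dtype=float) for c in BMIZ_COLS}
    fills = []
    for rng in _imputation_rngs(config):
        current = {c: v.copy() for c, v in bmiz_true.items()}
        for col, miss in holes.items():
            current[col] = _init_from_margins(bmiz_true[col], miss, rng)
        for _ in range(config.fcs_cycles if holes else 0):
            for col, miss in holes.items():
                other = [c for c in BMIZ_COLS if c != col]
                X = np.column_stack([base] + [current[c] for c in other])
                names = ["const"] + FCS_STATIC_PREDICTORS + other
                drawn = bayesian_linear_draw(
                    bmiz_true[col][~miss], X[~miss], X[miss], rng, names
                )
                current[col][miss] = drawn
        fills.append({col: current[col][holes[col]] for col in holes})
    return CompletedSet("FCS", _completed_panels(panel, holes, fills), config.seed)


# --------------------------------------------------------------------------
# MVNI
# --------------------------------------------------------------------------


def _mvn_da_chain(
    Z: np.ndarray, miss: np.ndarray, config: ImputationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Data-augmentation sampler for a joint multivariate-normal model.

    ``Z`` is an (n, p) data matrix with ``miss`` marking the cells to
    impute (already initialized).  Runs one chain; returns ``m`` completed
    copies saved every ``da_thin`` iterations after ``da_burnin``.
    """
    n, p = Z.shape
    Z = Z.copy()
    patterns: list[tuple[np.ndarray, np.ndarray]] = []
    if miss.any():
        uniq, inverse = np.unique(miss, axis=0, return_inverse=True)
        for k, pat in enumerate(uniq):
            if pat.any():
                patterns.append((np.flatnonzero(inverse == k), pat))
    saved: list[np.ndarray] = []
    total = config.da_burnin + config.m * config.da_thin
    for it in range(total):
        # P-step: (mu, Sigma) from the noninformative normal-inverse-Wishart posterior
        zbar = Z.mean(axis=0)
        centered = Z - zbar
        S = centered.T @ centered
        sigma = None
        for jitter in (0.0, 1e-8, 1e-6, 1e-4):
            try:
                scale = S + jitter * np.trace(S) / p * np.eye(p)
                sigma = invwishart.rvs(df=n - 1, scale=scale, random_state=rng)
                chol_sigma = cholesky(sigma, lower=True)
                break
            except (np.linalg.LinAlgError, ValueError):
                sigma = None
        if sigma is None:
            raise RuntimeError("covariance draw failed to be positive definite")
        mu = zbar + (chol_sigma @ rng.standard_normal(p)) / np.sqrt(n)
        # I-step: conditional-normal draws per missingness pattern
        for rows, pat in patterns:
            idx_m = np.flatnonzero(pat)
            idx_o = np.flatnonzero(~pat)
            s_oo = sigma[np.ix_(idx_o, idx_o)]
            s_mo = sigma[np.ix_(idx_m, idx_o)]
            k_gain = np.linalg.solve(s_oo, s_mo.T).T
            cond_cov = sigma[np.ix_(idx_m, idx_m)] - k_gain @ s_mo.T
            cond_cov = (cond_cov + cond_cov.T) / 2.0
            for jitter in (0.0, 1e-10, 1e-8):
                try:
                    chol_c = cholesky(cond_cov + jitter * np.eye(len(idx_m)), lower=True)
                    break
                except np.linalg.LinAlgError:
                    chol_c = None
            if chol_c is None:
                raise RuntimeError("conditional covariance not positive definite")
            resid_o = Z[np.ix_(rows, idx_o)] - mu[idx_o]
            mean_m = mu[idx_m] + resid_o @ k_gain.T
            noise = rng.standard_normal((len(rows), len(idx_m))) @ chol_c.T
            Z[np.ix_(rows, idx_m)] = mean_m + noise
        if it >= config.da_burnin and (it - config.da_burnin + 1) % config.da_thin == 0:
            saved.append(Z.copy())
    return saved[: config.m]


def mvni_impute(panel: pd.DataFrame, config: ImputationConfig) -> CompletedSet:
    """Joint multivariate-normal imputation by data augmentation.

    The joint model covers the exposure at all five waves, the outcome at
    all five waves and the time-invariant covariates; only the exposure
    cells are ever missing, so the normality assumption bears on the
    imputed variables alone and the binaries act as complete predictors.
    """
    holes = _check_holes(panel)
    Z = panel[MVN_COLS].to_numpy(dtype=float)
    miss = np.zeros_like(Z, dtype=bool)
    for col, colmiss in holes.items():
        miss[:, MVN_COLS.index(col)] = colmiss
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    Z0 = Z.copy()
    for col, colmiss in holes.items():
        j = MVN_COLS.index(col)
        Z0[:, j] = _init_from_margins(Z[:, j], colmiss, rng)
    if holes:
        completed = _mvn_da_chain(Z0, miss, config, rng)
    else:
        completed = [Z0.copy() for _ in range(config.m)]
    fills = [
        {col: Zc[holes[col], MVN_COLS.index(col)] for col in holes} for Zc in completed
    ]
    return CompletedSet("MVNI", _completed_panels(panel, holes, fills), config.seed)


# --------------------------------------------------------------------------
# two-fold FCS
# --------------------------------------------------------------------------


def twofold_predictor_waves(t: int, width: int) -> list[int]:
    """Waves inside the two-fold time window around wave ``t``."""
    return [j for j in range(max(1, t - width), min(N_WAVES, t + width) + 1)]


def twofold_predictor_columns(t: int, width: int) -> list[str]:
    """Predictor columns for imputing the exposure at wave ``t``."""
    waves = twofold_predictor_waves(t, width)
    cols = [f"bmiz{j}" for j in waves if j != t]
    cols += [f"sleep_prob{j}" for j in waves]
    cols += TIME_INVARIANT_COLS
    return cols


def twofold_fcs_impute(panel: pd.DataFrame, config: ImputationConfig) -> CompletedSet:
    """Two-fold FCS: imputation restricted to a window of adjacent waves.

    For each time point ``t`` the model uses the exposure and outcome at
    waves within ``window_width`` of ``t`` plus all time-invariant
    variables; time points are visited in order ``twofold_among`` times,
    with ``twofold_within`` refinement cycles at each.
    """
    holes = _check_holes(panel)
    w = config.window_width
    data = {c: panel[c].to_numpy(dtype=float) for c in MVN_COLS}
    n = len(panel)
    fills = []
    for rng in _imputation_rngs(config):
        current = {c: v.copy() for c, v in data.items()}
        for col, miss in holes.items():
            current[col] = _init_from_margins(data[col], miss, rng)
        for _ in range(config.twofold_among if holes else 0):
            for t in range(1, N_WAVES + 1):
                col = f"bmiz{t}"
                if col not in holes:
                    continue
                miss = holes[col]
                pred_cols = twofold_predictor_columns(t, w)
                for _ in range(config.twofold_within):
                    X = np.column_stack(
                        [np.ones(n)] + [current[c] for c in pred_cols]
                    )
                    drawn = bayesian_linear_draw(
                        data[col][~miss], X[~miss], X[miss], rng, ["const"] + pred_cols
                    )
                    current[col][miss] = drawn
        fills.append({col: current[col][holes[col]] for col in holes})
    return CompletedSet(
        f"TWOFOLD_W{w}", _completed_panels(panel, holes, fills), config.seed, width=w
    )


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

METHODS = ("FCS", "MVNI", "TWOFOLD_W1", "TWOFOLD_W2")


def impute(panel: pd.DataFrame, method: str, config: ImputationConfig) -> CompletedSet:
    """Run the named imputation method on a masked panel."""
    method = method.upper()
    if method == "FCS":
        return fcs_impute(panel, config)
    if method == "MVNI":
        return mvni_impute(panel, config)
    if method.startswith("TWOFOLD"):
        width = config.window_width
        if "_W" in method:
            width = int(method.rsplit("_W", 1)[1])
        from dataclasses import replace

        return twofold_fcs_impute(panel, replace(config, window_width=width))
    raise ValueError(f"unknown imputation method {method!r}")
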