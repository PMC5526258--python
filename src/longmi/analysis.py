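"""Target analysis: lagged-exposure GEE and Rubin's-rules pooling.

The substantive model is a marginal (population-average) logistic
regression of the wave-j outcome on the wave-(j-1) exposure, the
time-invariant confounders and the wave-(j-1) outcome, over waves 2-5,
estimated by generalized estimating equations with an unstructured 4x4
working correlation and robust (sandwich) standard errors.  Because every
analyzable child contributes exactly four rows, the GEE is solved by a
fully vectorized Fisher-scoring loop specialized to balanced clusters,
which is orders of magnitude faster than a generic implementation at the
cluster counts a simulation study needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, t as t_dist

from .cohort import N_WAVES

__all__ = [
    "ANALYSIS_COVARIATES",
    "GeeEstimate",
    "PooledEstimate",
    "build_analysis_long",
    "fit_gee",
    "complete_case_estimate",
    "pool_completed",
    "rubin_pool",
]

ANALYSIS_COVARIATES = ["m_education", "sex", "birthweight", "m_age"]
# design column order; the exposure coefficient is the estimand
DESIGN_COLS = ["const", "bmiz_lag"] + ANALYSIS_COVARIATES + ["sleep_lag"]
_EXPOSURE_IDX = 1


@dataclass
class GeeEstimate:
    """Exposure log-odds ratio from one GEE fit."""

    beta1: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool
    n_clusters: int
    params: np.ndarray | None = None
    fallback_exchangeable: bool = False


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m per-imputation estimates."""

    estimate: float
    W: float
    B: float
    T: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    m: int


def build_analysis_long(panel: pd.DataFrame) -> pd.DataFrame:
    """Reshape a wide panel into the 4-rows-per-child analysis table.

    The row for wave ``j`` (j = 2..5) carries the outcome at wave ``j``,
    the exposure and the outcome at wave ``j - 1``, and the time-invariant
    confounders; the wave-5 exposure never enters the analysis.  Rows are
    ordered by (child, wave).
    """
    required = ANALYSIS_COVARIATES + [f"bmiz{j}" for j in range(1, N_WAVES)] + [
        f"sleep_prob{j}" for j in range(1, N_WAVES + 1)
    ]
    missing_cols = [c for c in required if c not in panel.columns]
    if missing_cols:
        raise KeyError(f"panel lacks required columns: {missing_cols}")
    n = len(panel)
    frames = []
    for j in range(2, N_WAVES + 1):
        frames.append(
            pd.DataFrame(
                {
                    "child": np.arange(n),
                    "wave": j,
                    "sleep": panel[f"sleep_prob{j}"].to_numpy(dtype=float),
                    "bmiz_lag": panel[f"bmiz{j - 1}"].to_numpy(dtype=float),
                    "m_education": panel["m_education"].to_numpy(dtype=float),
                    "sex": panel["sex"].to_numpy(dtype=float),
                    "birthweight": panel["birthweight"].to_numpy(dtype=float),
                    "m_age": panel["m_age"].to_numpy(dtype=float),
                    "sleep_lag": panel[f"sleep_prob{j - 1}"].to_numpy(dtype=float),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    return long.sort_values(["child", "wave"], kind="stable").reset_index(drop=True)


def _logistic_irls(X: np.ndarray, y: np.ndarray, maxiter: int = 40) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    for _ in range(maxiter):
        mu = expit(X @ beta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def fit_gee(long_table: pd.DataFrame, maxiter: int = 500, tol: float = 1e-6) -> GeeEstimate:
    """Fit the marginal logistic GEE on a balanced 4-wave analysis table.

    Fisher scoring with an unstructured moment-estimated working
    correlation; the working correlation being common to all clusters, each
    update needs only one 4x4 inverse.  Robust sandwich covariance; Wald
    95% CI.  Falls back to an exchangeable working correlation if the
    unstructured moment estimate loses positive definiteness.
    """
    tab = long_table.sort_values(["child", "wave"], kind="stable")
    counts = tab.groupby("child").size()
    if (counts != N_WAVES - 1).any():
        raise ValueError("analysis table must have exactly 4 rows per child")
    n = len(counts)
    if n < 2:
        raise ValueError("need at least 2 clusters")
    T = N_WAVES - 1
    y = tab["sleep"].to_numpy(dtype=float).reshape(n, T)
    Xcols = [np.ones(n * T)] + [tab[c].to_numpy(dtype=float) for c in DESIGN_COLS[1:]]
    p = len(Xcols)
    X = np.column_stack(Xcols).reshape(n, T, p)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("analysis table contains missing values")

    X_flat = X.reshape(n * T, p)
    beta = _logistic_irls(X_flat, y.ravel())
    converged = False
    fallback = False
    R = np.eye(T)
    for _ in range(maxiter):
        mu = expit((X_flat @ beta).reshape(n, T))
        v = mu * (1 - mu)
        s = np.sqrt(v)
        e = (y - mu) / s                                  # Pearson residuals
        phi = float((e * e).sum() / (n * T - p))
        R = (e.T @ e) / ((n - p) * phi)
        R = (R + R.T) / 2.0
        # guard: normalize to a correlation matrix and check definiteness
        d = np.sqrt(np.clip(np.diag(R), 1e-12, None))
        R = R / np.outer(d, d)
        if np.linalg.eigvalsh(R).min() < 1e-8:
            rho = float(np.clip((R.sum() - T) / (T * (T - 1)), -0.99 / (T - 1), 0.99))
            R = np.full((T, T), rho)
            np.fill_diagonal(R, 1.0)
            fallback = True
        Rinv = np.linalg.inv(R)
        Xs = X * s[:, :, None]                            # A^{1/2} X per cluster
        Xs_flat = Xs.reshape(n * T, p)
        q = (e @ Rinv).reshape(n * T)                     # (R^-1 e_i) stacked
        H = Xs_flat.T @ np.matmul(Rinv, Xs).reshape(n * T, p)
        U = Xs_flat.T @ q
        step = np.linalg.solve(H, U)
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    # sandwich covariance (phi cancels between bread and meat)
    mu = expit((X_flat @ beta).reshape(n, T))
    s = np.sqrt(mu * (1 - mu))
    e = (y - mu) / s
    Xs = X * s[:, :, None]
    Rinv = np.linalg.inv(R)
    H = Xs.reshape(n * T, p).T @ np.matmul(Rinv, Xs).reshape(n * T, p)
    q = e @ Rinv                                          # (n, T)
    u_n = np.matmul(q[:, None, :], Xs)[:, 0, :]           # per-cluster scores
    meat = u_n.T @ u_n
    Hinv = np.linalg.inv(H)
    cov = Hinv @ meat @ Hinv
    se = float(np.sqrt(cov[_EXPOSURE_IDX, _EXPOSURE_IDX]))
    b1 = float(beta[_EXPOSURE_IDX])
    zcrit = norm.ppf(0.975)
    return GeeEstimate(
        beta1=b1,
        se=se,
        ci_low=b1 - zcrit * se,
        ci_high=b1 + zcrit * se,
        converged=converged,
        n_clusters=n,
        params=beta,
        fallback_exchangeable=fallback,
    )


def complete_case_estimate(masked_panel: pd.DataFrame) -> GeeEstimate:
    """GEE after dropping children with any missing exposure at waves 2-4.

    The wave-5 exposure never enters the lagged analysis, so its
    missingness does not exclude a child.
    """
    drop = np.zeros(len(masked_panel), dtype=bool)
    for j in (2, 3, 4):
        drop |= masked_panel[f"bmiz{j}"].isna().to_numpy()
    kept = masked_panel.loc[~drop].reset_index(drop=True)
    if len(kept) < 2:
        raise ValueError("fewer than 2 complete cases remain")
    return fit_gee(build_analysis_long(kept))


def rubin_pool(estimates: list[GeeEstimate], alpha: float = 0.05) -> PooledEstimate:
    """Combine per-imputation GEE estimates by Rubin's rules.

    ``W`` is the mean squared standard error, ``B`` the sample variance of
    the point estimates, ``T = W + (1 + 1/m) B``; the CI uses Rubin's
    classic degrees of freedom (normal when ``B = 0``).
    """
    ests = [e for e in estimates if e.converged]
    m = len(ests)
    if m < 2:
        raise ValueError("need at least 2 converged estimates to pool")
    q = np.array([e.beta1 for e in ests])
    w = np.array([e.se**2 for e in ests])
    qbar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    total = W + (1 + 1 / m) * B
    se = float(np.sqrt(total))
    if B > 0:
        r = (1 + 1 / m) * B / W
        df = (m - 1) * (1 + 1 / r) ** 2
        crit = float(t_dist.ppf(1 - alpha / 2, df))
    else:
        df = np.inf
        crit = float(norm.ppf(1 - alpha / 2))
    return PooledEstimate(
        estimate=qbar,
        W=W,
        B=B,
        T=total,
        se=se,
        df=float(df),
        ci_low=qbar - crit * se,
        ci_high=qbar + crit * se,
        m=m,
    )


def pool_completed(completed, n_failures_out: list | None = None) -> PooledEstimate:
    """Fit the GEE on every completed panel and pool by Rubin's rules."""
    fits = [fit_gee(build_analysis_long(panel)) for panel in completed.panels]
    if n_failures_out is not None:
        n_failures_out.append(sum(not f.converged for f in fits))
    return rubin_pool(fits)
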