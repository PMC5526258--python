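"""Tests of the three MI engines and the posterior-predictive draw primitive."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from longmi.analysis import pool_completed
from longmi.impute import (
    BMIZ_COLS,
    DegenerateModelError,
    ImputationConfig,
    bayesian_linear_draw,
    fcs_impute,
    impute,
    mvni_impute,
    twofold_fcs_impute,
    twofold_predictor_columns,
    twofold_predictor_waves,
    _mvn_da_chain,
)
from longmi.missingness import MissingnessSpec, apply_missingness


class TestBayesianLinearDraw:
    def test_no_missing_rows_returns_empty(self):
        rng = np.random.default_rng(0)
        out = bayesian_linear_draw(np.ones(10), np.ones((10, 1)), np.empty((0, 1)), rng)
        assert out.size == 0

    def test_noiseless_limit_reproduces_fit(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(500), rng.normal(size=500)])
        beta = np.array([1.0, -2.0])
        y = X @ beta  # exactly linear
        X_new = np.array([[1.0, 0.5], [1.0, -1.0]])
        drawn = bayesian_linear_draw(y, X, X_new, rng)
        np.testing.assert_allclose(drawn, X_new @ beta, atol=1e-6)

    def test_draw_variance_matches_posterior_predictive_oracle(self):
        """On a 20-row toy the between-draw variance of an imputed value
        matches the analytic posterior-predictive variance
        sigma_hat^2 (1 + leverage) * dof / (dof - 2)."""
        rng = np.random.default_rng(2)
        n, p = 20, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = X @ np.array([0.5, 1.0, -1.0]) + rng.normal(0, 0.8, n)
        x0 = np.array([[1.0, 0.3, -0.2]])
        beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_hat
        dof = n - p
        s2 = resid @ resid / dof
        leverage = float((x0 @ np.linalg.inv(X.T @ X) @ x0.T)[0, 0])
        analytic = s2 * (1 + leverage) * dof / (dof - 2)  # t predictive variance
        draws = np.array(
            [bayesian_linear_draw(y, X, x0, np.random.default_rng(s))[0] for s in range(6000)]
        )
        assert draws.var(ddof=1) == pytest.approx(analytic, rel=0.15)
        assert draws.var(ddof=1) > 0

    def test_exactly_collinear_design_raises(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(DegenerateModelError, match="rank-deficient"):
            bayesian_linear_draw(rng.normal(size=30), X, X[:2], rng, ["const", "x", "x2"])

    def test_more_columns_than_rows_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(DegenerateModelError):
            bayesian_linear_draw(np.ones(3), np.eye(3), np.eye(3), rng)


class TestNoOpOnCompleteData:
    @pytest.mark.parametrize("engine", [fcs_impute, mvni_impute, twofold_fcs_impute])
    def test_complete_panel_copies_unchanged(self, panel_small, quick_imp_config, engine):
        completed = engine(panel_small, quick_imp_config)
        assert completed.m == quick_imp_config.m
        for copy in completed.panels:
            pd.testing.assert_frame_equal(copy, panel_small)


class TestObservedCellPreservation:
    @pytest.mark.parametrize("method", ["FCS", "MVNI", "TWOFOLD_W1", "TWOFOLD_W2"])
    def test_observed_values_bitwise_identical(self, masked_small, quick_imp_config, method):
        completed = impute(masked_small, method, quick_imp_config)
        obs_mask = {c: ~masked_small[c].isna().to_numpy() for c in BMIZ_COLS}
        for copy in completed.panels:
            assert not copy.isna().any().any()
            for c in BMIZ_COLS:
                np.testing.assert_array_equal(
                    copy[c].to_numpy()[obs_mask[c]], masked_small[c].to_numpy()[obs_mask[c]]
                )
            other = [c for c in masked_small.columns if c not in BMIZ_COLS]
            pd.testing.assert_frame_equal(copy[other], masked_small[other])

    @pytest.mark.parametrize("method", ["FCS", "MVNI", "TWOFOLD_W1"])
    def test_proper_imputation_varies_between_copies(self, masked_small, quick_imp_config, method):
        completed = impute(masked_small, method, quick_imp_config)
        holes = masked_small["bmiz5"].isna().to_numpy()
        vals = np.array([c["bmiz5"].to_numpy()[holes] for c in completed.panels])
        assert vals.std(axis=0).min() > 0


class TestMaskedEntryRecovery:
    @pytest.mark.parametrize("method", ["FCS", "MVNI", "TWOFOLD_W1", "TWOFOLD_W2"])
    def test_mcar_masked_means_recovered(self, panel_medium, method):
        """Under MCAR masking of a known complete panel, the mean of the
        imputed values agrees with the mean of the masked true values."""
        pattern = apply_missingness(
            panel_medium, MissingnessSpec(mechanism="MCAR", target_final=0.25), seed=21
        )
        masked = pattern.mask(panel_medium)
        cfg = ImputationConfig(m=5, fcs_cycles=5, da_burnin=60, da_thin=10, twofold_among=5, seed=22)
        completed = impute(masked, method, cfg)
        holes = masked["bmiz4"].isna().to_numpy()
        truth = panel_medium["bmiz4"].to_numpy()[holes].mean()
        imputed = np.mean([c["bmiz4"].to_numpy()[holes].mean() for c in completed.panels])
        assert imputed == pytest.approx(truth, abs=0.05)


class TestMvniEngine:
    def test_bivariate_normal_toy_recovers_correlation(self):
        """DA imputation of a bivariate normal with rho = 0.6 and 30% MCAR
        holes in the second coordinate recovers the correlation."""
        rng = np.random.default_rng(30)
        n, rho = 2000, 0.6
        Z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        miss = np.zeros_like(Z, dtype=bool)
        miss[:, 1] = rng.random(n) < 0.3
        Z0 = Z.copy()
        Z0[miss] = np.nan
        obs = Z0[~miss[:, 1], 1]
        Z0[miss[:, 1], 1] = rng.choice(obs, miss[:, 1].sum())
        cfg = ImputationConfig(m=5, da_burnin=100, da_thin=20)
        completed = _mvn_da_chain(Z0, miss, cfg, rng)
        pooled_corr = np.mean([np.corrcoef(Zc.T)[0, 1] for Zc in completed])
        assert pooled_corr == pytest.approx(rho, abs=0.05)


class TestTwofoldStructure:
    def test_window_waves(self):
        assert twofold_predictor_waves(3, 1) == [2, 3, 4]
        assert twofold_predictor_waves(5, 1) == [4, 5]
        assert twofold_predictor_waves(1, 1) == [1, 2]
        assert twofold_predictor_waves(3, 2) == [1, 2, 3, 4, 5]

    @pytest.mark.parametrize("t", range(1, 6))
    @pytest.mark.parametrize("width", [1, 2, 3])
    def test_window_containment(self, t, width):
        for col in twofold_predictor_columns(t, width):
            if col[-1].isdigit():
                assert abs(int(col[-1]) - t) <= width

    def test_width_four_predictors_equal_fcs(self):
        """With window width 4 every time point sees the full FCS predictor
        set, so the two methods use identical models."""
        from longmi.impute import FCS_STATIC_PREDICTORS

        for t in range(1, 6):
            fcs_set = set(FCS_STATIC_PREDICTORS) | {c for c in BMIZ_COLS if c != f"bmiz{t}"}
            assert set(twofold_predictor_columns(t, 4)) == fcs_set

    def test_width_four_estimates_agree_with_fcs(self, dgm):
        """Pooled exposure estimates from two-fold FCS with width 4 and from
        standard FCS agree within combined between-imputation noise."""
        from longmi.cohort import generate_cohort

        panel = generate_cohort(1200, dgm, seed=31)
        pattern = apply_missingness(panel, MissingnessSpec(mechanism="MCAR", target_final=0.25), seed=32)
        masked = pattern.mask(panel)
        cfg = ImputationConfig(m=8, fcs_cycles=5, twofold_among=5, window_width=4, seed=33)
        pooled_fcs = pool_completed(fcs_impute(masked, cfg))
        pooled_tf = pool_completed(twofold_fcs_impute(masked, cfg))
        noise = 4 * np.sqrt((pooled_fcs.B + pooled_tf.B) / cfg.m)
        assert abs(pooled_fcs.estimate - pooled_tf.estimate) <= max(noise, 0.02)


class TestConfigValidation:
    def test_rejects_single_imputation(self):
        with pytest.raises(ValueError):
            ImputationConfig(m=1)

    def test_rejects_holes_outside_exposure(self, panel_small, quick_imp_config):
        broken = panel_small.copy()
        broken.loc[0, "sleep_prob3"] = np.nan
        with pytest.raises(ValueError, match="bmiz"):
            fcs_impute(broken, quick_imp_config)

    def test_unknown_method_rejected(self, masked_small, quick_imp_config):
        with pytest.raises(ValueError):
            impute(masked_small, "LOCF", quick_imp_config)
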