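"""Tests of the lagged-exposure GEE, the complete-case rule and Rubin pooling.

The GEE solver is cross-checked against statsmodels' generic GEE
implementation, which serves as the independent oracle.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longmi.analysis import (
    GeeEstimate,
    build_analysis_long,
    complete_case_estimate,
    fit_gee,
    rubin_pool,
)
from longmi.cohort import DGMParams, SleepFollowupParams, calibrate_dgm, generate_cohort
from longmi.missingness import MissingnessSpec, apply_missingness


class TestBuildAnalysisLong:
    def test_shape_and_lag_mapping(self, panel_small):
        long = build_analysis_long(panel_small)
        assert len(long) == 4 * len(panel_small)
        assert (long.groupby("child").size() == 4).all()
        w2 = long[long["wave"] == 2].set_index("child")
        np.testing.assert_array_equal(w2["bmiz_lag"], panel_small["bmiz1"])
        np.testing.assert_array_equal(w2["sleep_lag"], panel_small["sleep_prob1"])
        # the wave-5 exposure never enters the analysis table
        assert "bmiz5" not in long.columns
        w5 = long[long["wave"] == 5].set_index("child")
        np.testing.assert_array_equal(w5["bmiz_lag"], panel_small["bmiz4"])

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            build_analysis_long(pd.DataFrame({"bmiz1": [1.0]}))


class TestFitGee:
    def test_agrees_with_statsmodels_oracle(self, dgm):
        import statsmodels.api as sm

        panel = generate_cohort(1500, dgm, seed=41)
        long = build_analysis_long(panel)
        ours = fit_gee(long)
        X = sm.add_constant(
            long[["bmiz_lag", "m_education", "sex", "birthweight", "m_age", "sleep_lag"]]
        ).to_numpy()
        oracle = sm.GEE(
            long["sleep"].to_numpy(),
            X,
            groups=long["child"].to_numpy(),
            time=(long["wave"] - 2).to_numpy(),
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Unstructured(),
        ).fit()
        np.testing.assert_allclose(ours.params, oracle.params, atol=2e-5)
        assert ours.se == pytest.approx(oracle.bse[1], rel=1e-4)
        assert ours.converged
        assert ours.ci_low < ours.beta1 < ours.ci_high

    def test_null_exposure_recovery(self):
        """With a null exposure effect and no random effects the estimate is
        within 2 robust SEs of zero at n = 50000."""
        from longmi.cohort import BmizTrajectoryParams

        dgm0 = calibrate_dgm(
            DGMParams(
                followup=SleepFollowupParams(lam1=0.0),
                bmiz=BmizTrajectoryParams(sigma_a=tuple((0.0,) * 3 for _ in range(3))),
            )
        )
        panel = generate_cohort(50_000, dgm0, seed=42)
        est = fit_gee(build_analysis_long(panel))
        assert abs(est.beta1) < 2 * est.se

    def test_independence_limit_matches_plain_logistic(self):
        """When rows are truly independent the GEE solution coincides with
        ordinary logistic regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(43)
        n = 20_000
        x = rng.normal(size=4 * n)
        eta = -1.5 + 0.3 * x
        y = (rng.random(4 * n) < 1 / (1 + np.exp(-eta))).astype(float)
        long = pd.DataFrame(
            {
                "child": np.repeat(np.arange(n), 4),
                "wave": np.tile([2, 3, 4, 5], n),
                "sleep": y,
                "bmiz_lag": x,
                "m_education": 0.0,
                "sex": rng.integers(0, 2, 4 * n).astype(float),
                "birthweight": rng.normal(3.3, 0.5, 4 * n),
                "m_age": rng.normal(31, 5, 4 * n),
                "sleep_lag": rng.integers(0, 2, 4 * n).astype(float),
            }
        )
        long = long.drop(columns=["m_education"]).assign(m_education=rng.integers(0, 2, 4 * n).astype(float))
        gee = fit_gee(long)
        X = sm.add_constant(
            long[["bmiz_lag", "m_education", "sex", "birthweight", "m_age", "sleep_lag"]]
        ).to_numpy()
        glm = sm.GLM(long["sleep"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert abs(gee.beta1 - glm.params[1]) < 1e-3

    def test_rejects_unbalanced_table(self, panel_small):
        long = build_analysis_long(panel_small).iloc[:-1]
        with pytest.raises(ValueError, match="4 rows"):
            fit_gee(long)


class TestCompleteCaseRule:
    def test_rule_boundaries(self, panel_small):
        masked = panel_small.copy()
        # child 0 misses only the wave-5 exposure: retained
        masked.loc[0, "bmiz5"] = np.nan
        # child 1 misses only wave 3: all four rows dropped
        masked.loc[1, "bmiz3"] = np.nan
        est = complete_case_estimate(masked)
        assert est.n_clusters == len(panel_small) - 1

    def test_zero_missingness_equals_full_fit(self, panel_small):
        full = fit_gee(build_analysis_long(panel_small))
        cca = complete_case_estimate(panel_small)
        assert cca.beta1 == pytest.approx(full.beta1, abs=1e-12)
        assert cca.se == pytest.approx(full.se, abs=1e-12)

    def test_sample_size_shrinks_under_missingness(self, panel_small):
        pattern = apply_missingness(
            panel_small, MissingnessSpec(mechanism="MCAR", target_final=0.5), seed=44
        )
        est = complete_case_estimate(pattern.mask(panel_small))
        assert est.n_clusters < len(panel_small)


def _estimate(beta, se):
    return GeeEstimate(
        beta1=beta, se=se, ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se,
        converged=True, n_clusters=100,
    )


class TestRubinPool:
    def test_hand_worked_example(self):
        pooled = rubin_pool([_estimate(b, 0.02) for b in (0.10, 0.12, 0.14)])
        assert pooled.estimate == pytest.approx(0.12)
        assert pooled.W == pytest.approx(4e-4)
        assert pooled.B == pytest.approx(4e-4)
        assert pooled.T == pytest.approx(9.333e-4, rel=1e-3)
        assert pooled.se == pytest.approx(0.03055, abs=1e-5)

    def test_degenerate_pooling(self):
        pooled = rubin_pool([_estimate(0.1, 0.02)] * 5)
        assert pooled.estimate == 0.1
        assert pooled.se == pytest.approx(0.02)
        assert pooled.B == 0.0
        assert np.isinf(pooled.df)

    def test_requires_two_estimates(self):
        with pytest.raises(ValueError):
            rubin_pool([_estimate(0.1, 0.02)])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        betas=st.lists(st.floats(-1, 1), min_size=2, max_size=20),
        se=st.floats(1e-3, 1.0),
    )
    def test_total_variance_dominates_within(self, betas, se):
        pooled = rubin_pool([_estimate(b, se) for b in betas])
        assert pooled.T >= pooled.W - 1e-15
        assert pooled.se >= np.sqrt(pooled.W) - 1e-12
        assert pooled.ci_low <= pooled.estimate <= pooled.ci_high
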