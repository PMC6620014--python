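"""RPC/APC regressions, cohort binning, transforms and the
cross-classified mixed model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from riskpc import (PanelDataset, SimCondition, bin_cohorts, compute_risk_index,
                    fit_apc_hapc, fit_apc_ols, fit_risk_model, fit_rpc_hapc,
                    fit_rpc_ols, log1p_outcome, simulate_nhanes_like,
                    simulate_study2)


class TestFitRpcOls:
    def test_identity_outcome(self):
        """outcome == risk exactly: slope 1 on the raw scale, null cohort
        and period slopes, R^2 = 1."""
        rng = np.random.default_rng(0)
        n = 500
        risk = rng.standard_normal(n)
        ds = PanelDataset(pd.DataFrame({
            "outcome": risk, "cohort": rng.normal(1950, 10, n),
            "period": rng.normal(1990, 5, n)}))
        fit = fit_rpc_ols(ds, risk, standardize_numeric=False)
        assert fit.risk_slope_star == pytest.approx(1.0, abs=1e-9)
        assert fit.cohort_slope_star == pytest.approx(0.0, abs=1e-9)
        assert fit.period_slope_star == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_minimum_norm_oracle_small(self):
        """<=10-row instances agree with an independent pinv-based
        minimum-norm solver to 10 significant digits."""
        rng = np.random.default_rng(1)
        for rows in (6, 8, 10):
            risk = rng.standard_normal(rows)
            ds = PanelDataset(pd.DataFrame({
                "outcome": rng.standard_normal(rows),
                "cohort": rng.normal(1950, 10, rows),
                "period": rng.normal(1990, 5, rows)}))
            fit = fit_rpc_ols(ds, risk, standardize_numeric=False)
            X = np.column_stack([np.ones(rows), risk,
                                 ds.col("cohort"), ds.col("period")])
            oracle = np.linalg.pinv(X) @ ds.col("outcome")
            np.testing.assert_allclose(fit.params.to_numpy(), oracle,
                                       rtol=1e-10)

    def test_null_cohort_recovered(self):
        """Data generated with no cohort effect and a well-mixed risk
        index: both extra slopes come back near zero."""
        ds = simulate_study2(SimCondition(0.4, 0.4, 0.2, gamma=0.0,
                                          n=10_000, seed=3))
        fit_r = fit_risk_model(ds, ["sep", "activity"],
                               outcome="baseline_outcome")
        risk = compute_risk_index(fit_r, ds)
        fit = fit_rpc_ols(ds, risk)
        assert abs(fit.cohort_slope_star) < 0.05
        assert abs(fit.period_slope_star) < 0.05
        assert not fit.rank_deficient

    def test_exactly_singular_sets_flag(self):
        """A risk index that *is* standardized age makes the design
        exactly singular: the fit is still produced, flagged, with the
        minimum-norm coefficients."""
        ds = simulate_study2(SimCondition(0.4, 0, 0, gamma=0.2,
                                          n=2000, seed=4))
        age = ds.col("age")
        risk = (age - age.mean()) / age.std()
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_rpc_ols(ds, risk)
        assert fit.rank_deficient

    def test_misaligned_lengths(self):
        ds = simulate_study2(SimCondition(0.4, 0.2, 0, gamma=0.2,
                                          n=200, seed=5))
        with pytest.raises(ValueError, match="length"):
            fit_rpc_ols(ds, np.ones(100))


class TestFitApcOls:
    def test_identification_problem_raises(self):
        """All-categorical age + period + cohort with only reference
        levels dropped is singular: the identification problem."""
        ds = simulate_study2(SimCondition(0.2, 0.2, 0.2, gamma=0.2,
                                          n=3000, seed=6))
        t = ds.table.copy()
        t["age"] = t.age.astype(int)
        t["period"] = t.period.round().astype(int).astype(str)
        t["cohort"] = (t.period.astype(int) - t.age).astype(str)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_apc_ols(PanelDataset(t), mode="categorical",
                        age_as="categorical")

    def test_numeric_variant_recovers_generating_slopes(self, study2_panel):
        fit = fit_apc_ols(study2_panel, mode="numeric",
                          covariates=["sep", "activity"])
        truth = {"age": 0.4, "sep": 0.2, "activity": 0.2, "cohort": 0.6}
        for name, value in truth.items():
            est = fit.params[name]
            se = fit.standard_errors[name]
            assert abs(est - value) < 3 * se, name

    def test_apc_variance_inflation_vs_rpc(self):
        """On the survey-style fixture the categorical APC fit has
        larger period/cohort standard errors than the RPC fit on
        average (near-collinearity inflates the APC variance)."""
        ds = simulate_nhanes_like(n=12_000, seed=9)
        from riskpc import predicted_age_index, run_demo  # noqa: F401
        from riskpc.demo import RISK_COVARIATES, _period_labels
        from riskpc.risk import predicted_age_index
        risk = predicted_age_index(ds, RISK_COVARIATES)
        t = ds.table.copy()
        t["log_score"] = log1p_outcome(ds.col("score"))
        t["cohort_bin"] = bin_cohorts(ds.col("cohort").astype(int), width=5)
        t["period_label"] = _period_labels(t["period"].to_numpy())
        work = PanelDataset(t)
        rpc = fit_rpc_ols(work, risk, cohort_as="categorical",
                          period_as="categorical", outcome="log_score",
                          cohort_col="cohort_bin", period_col="period_label")
        apc = fit_apc_ols(work, mode="categorical", outcome="log_score",
                          cohort_col="cohort_bin", period_col="period_label")
        shared = [i for i in rpc.params.index
                  if i.startswith(("cohort[", "period["))]
        assert (apc.standard_errors[shared].mean()
                >= rpc.standard_errors[shared].mean())


class TestBinCohorts:
    @pytest.mark.parametrize("year,label", [
        (1947, "1946-1950"), (1950, "1946-1950"), (1951, "1951-1955"),
        (1946, "1946-1950"), (1921, "1921-1925"),
    ])
    def test_five_year_right_closed_bins(self, year, label):
        out = bin_cohorts([1921, year], width=5)
        assert str(out[1]) == label

    def test_width_one_identity(self):
        years = [1950, 1951, 1952]
        assert [str(v) for v in bin_cohorts(years, width=1)] == \
            ["1950", "1951", "1952"]

    @settings(derandomize=True, max_examples=50)
    @given(years=st.lists(st.integers(min_value=1900, max_value=2000),
                          min_size=1, max_size=20),
           width=st.integers(min_value=1, max_value=10))
    def test_total_function_partitions_years(self, years, width):
        """Every integer year lands in exactly one bin and the bin
        bounds bracket it."""
        out = bin_cohorts(years, width=width)
        for year, label in zip(years, out):
            if width == 1:
                assert str(label) == str(year)
            else:
                start, end = map(int, str(label).split("-"))
                assert start <= year <= end
                assert end - start == width - 1

    def test_rejects_non_integer_years(self):
        with pytest.raises(ValueError, match="integer"):
            bin_cohorts([1950.5])


class TestLog1p:
    def test_anchor_values(self):
        np.testing.assert_allclose(log1p_outcome([0.0, np.e - 1]), [0.0, 1.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            log1p_outcome([1.0, -0.5])

    def test_reduces_skewness_of_fixture_scores(self):
        score = simulate_nhanes_like(n=20_000, seed=10).col("score")
        assert stats.skew(log1p_outcome(score)) < stats.skew(score)


class TestHapc:
    @staticmethod
    def _crossed_panel(seed=11, n=10_000, J=6, K=15,
                       period_sd=0.5, cohort_sd=1.0):
        """Crossed design whose realized random-effect moments are
        normalized exactly to the nominal variance components."""
        rng = np.random.default_rng(seed)
        per = rng.integers(0, J, n)
        coh = rng.integers(0, K, n)
        risk = rng.standard_normal(n)

        def draw(k, sd):
            raw = rng.standard_normal(k)
            raw -= raw.mean()
            return raw / raw.std() * sd

        tau, lam = draw(J, period_sd), draw(K, cohort_sd)
        y = 1.0 + 0.5 * risk + tau[per] + lam[coh] + rng.standard_normal(n)
        table = pd.DataFrame({
            "outcome": y, "risk": risk,
            "period": pd.Categorical([f"p{j}" for j in per]),
            "cohort": pd.Categorical([f"c{k:02d}" for k in coh])})
        return PanelDataset(table), tau, lam

    def test_variance_component_recovery(self):
        ds, tau, lam = self._crossed_panel()
        fit = fit_rpc_hapc(ds, ds.col("risk"))
        vc = fit.variance_components
        assert vc["period"] == pytest.approx(0.25, rel=0.25)
        assert vc["cohort"] == pytest.approx(1.0, rel=0.25)
        assert vc["residual"] == pytest.approx(1.0, rel=0.25)
        assert fit.fixed_slopes["risk"] == pytest.approx(0.5, abs=0.05)

    def test_zero_period_variance_estimated_near_zero(self):
        ds, _, _ = self._crossed_panel(seed=12, period_sd=0.0)
        fit = fit_rpc_hapc(ds, ds.col("risk"))
        assert fit.variance_components["period"] < 0.01

    def test_blups_shrunken_toward_zero(self):
        """Predicted random intercepts shrink relative to fixed-effect
        dummy estimates of the same levels."""
        ds, tau, lam = self._crossed_panel(seed=13, n=4000, K=8)
        fit = fit_rpc_hapc(ds, ds.col("risk"))
        fe = fit_rpc_ols(ds, ds.col("risk"), cohort_as="categorical",
                         period_as="categorical",
                         standardize_numeric=False)
        dummy = fe.cohort_slope_star
        ref = fe.reference_levels["cohort"]
        full = pd.concat([pd.Series({ref: 0.0}), dummy]).sort_index()
        full_centered = full - full.mean()
        blup = fit.cohort_random_intercepts.sort_index()
        blup_centered = blup - blup.mean()
        assert blup_centered.abs().sum() <= full_centered.abs().sum() * 1.02

    def test_random_intercepts_sum_near_zero(self):
        ds, _, _ = self._crossed_panel(seed=14)
        fit = fit_rpc_hapc(ds, ds.col("risk"))
        assert abs(fit.cohort_random_intercepts.mean()) < 0.15
        assert abs(fit.period_random_intercepts.mean()) < 0.15

    def test_apc_hapc_quadratic_age_option(self):
        ds, _, _ = self._crossed_panel(seed=15, n=3000)
        ds.table["age"] = np.random.default_rng(16).uniform(30, 80, 3000)
        fit = fit_apc_hapc(ds, quadratic_age=True)
        assert set(fit.fixed_slopes.index) == {"age", "age_sq"}
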