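"""Aggregation, Min-Max normalization, relation fitting, Wald test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from insolegait.cohort import (RecoveryTrendModel, RelationFit, aggregate_visit,
                               fit_relation, minmax_normalize,
                               regular_ratio_regression, relation_transform,
                               select_best, wald_slope_test, wald_slope_test_xy)
from insolegait.data import PARAMETER_NAMES, SideRole
from insolegait.landmarks import NON_REGULAR, REGULAR
from insolegait.parameters import StrideParameters


def _params(**kw):
    base = {name: None for name in PARAMETER_NAMES}
    base["F_total_max"] = 1.0
    base.update(kw)
    return StrideParameters(**base)


class TestAggregateVisit:
    def test_arithmetic_mean(self):
        agg = aggregate_visit(
            [_params(F_total_max=1.0), _params(F_total_max=1.2)],
            [REGULAR, REGULAR], subject_id="S1", side_role="injured",
            days_after_surgery=10)
        assert agg.param_means["F_total_max"] == pytest.approx(1.1)
        assert agg.n_strides == 2

    def test_absent_parameters_skip_the_mean(self):
        """A single-maximum stride contributes nothing to the inter-max
        mean; the aggregate averages only strides where it is present."""
        agg = aggregate_visit(
            [_params(Time_inter_max=None), _params(Time_inter_max=0.4)],
            [NON_REGULAR, REGULAR], subject_id="S1", side_role="healthy",
            days_after_surgery=40)
        assert agg.param_means["Time_inter_max"] == pytest.approx(0.4)
        assert agg.param_means["F_mean_TP"] is None

    def test_regular_ratio_and_empty_error(self):
        agg = aggregate_visit(
            [_params()] * 10, [REGULAR] * 3 + [NON_REGULAR] * 7,
            subject_id="S1", side_role="healthy", days_after_surgery=5)
        assert agg.regular_ratio == pytest.approx(0.3)
        with pytest.raises(ValueError):
            aggregate_visit([], [], subject_id="S1", side_role="healthy",
                            days_after_surgery=5)


class TestMinMax:
    def _table(self, rows):
        base = {name: np.nan for name in PARAMETER_NAMES}
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_basic_scaling(self):
        t = self._table([
            {"subject_id": "A", "side_role": "injured", "F_total_max": v}
            for v in (2.0, 4.0, 6.0)])
        out = minmax_normalize(t)
        np.testing.assert_allclose(out["F_total_max"], [0.0, 0.5, 1.0])

    def test_constant_subject_excluded(self):
        t = self._table([
            {"subject_id": "A", "side_role": "injured", "F_total_max": 5.0},
            {"subject_id": "A", "side_role": "injured", "F_total_max": 5.0}])
        out = minmax_normalize(t)
        assert out["F_total_max"].isna().all()

    def test_disjoint_subject_ranges_overlap_after_scaling(self):
        t = self._table(
            [{"subject_id": "A", "side_role": "injured", "F_total_max": v}
             for v in (1.0, 2.0)] +
            [{"subject_id": "B", "side_role": "injured", "F_total_max": v}
             for v in (100.0, 200.0)])
        out = minmax_normalize(t)
        np.testing.assert_allclose(out["F_total_max"], [0, 1, 0, 1])

    def test_pooled_scope_spans_both_sides(self):
        t = self._table([
            {"subject_id": "A", "side_role": "injured", "F_total_max": 0.0},
            {"subject_id": "A", "side_role": "healthy", "F_total_max": 10.0},
            {"subject_id": "A", "side_role": "injured", "F_total_max": 5.0}])
        pooled = minmax_normalize(t)
        np.testing.assert_allclose(pooled["F_total_max"], [0.0, 1.0, 0.5])
        per_side = minmax_normalize(t, scope="per_side")
        np.testing.assert_allclose(per_side["F_total_max"], [0.0, np.nan, 1.0])


class TestFitRelation:
    def test_exact_linear(self):
        x = np.arange(1.0, 11.0)
        fit = fit_relation(x, 2.0 + 0.5 * x, "linear")
        assert fit.beta1 == pytest.approx(0.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.fit_error == pytest.approx(0.0, abs=1e-12)

    def test_exact_logarithmic(self):
        x = np.arange(1.0, 21.0)
        fit = fit_relation(x, 1.0 + 2.0 * np.log(x), "logarithmic")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.beta1 == pytest.approx(2.0, abs=1e-9)

    def test_logarithmic_requires_x_ge_1(self):
        with pytest.raises(ValueError):
            fit_relation(np.array([0.5, 2.0, 3.0]), np.ones(3), "logarithmic")

    @pytest.mark.parametrize("relation", ["linear", "square", "cubic", "logarithmic"])
    def test_iterative_fit_matches_closed_form_ols(self, relation):
        """The capped iterative optimizer reduces to transform-then-OLS."""
        rng = np.random.default_rng(17)
        x = np.linspace(1.0, 175.0, 44)
        y = 0.3 + 0.004 * x + rng.normal(0, 0.1, 44)
        fit = fit_relation(x, y, relation)
        g = relation_transform(relation, x)
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(g), g]), y,
                                   rcond=None)
        assert fit.beta0 == pytest.approx(coef[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(coef[1], abs=1e-6)


class TestWaldTest:
    def test_constant_y_gives_t0_p1(self):
        t, df, p = wald_slope_test_xy(np.arange(10.0), np.full(10, 3.0))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_noise_free_slope_p_vanishes(self):
        x = np.arange(1.0, 20.0)
        t, df, p = wald_slope_test_xy(x, 1.0 + 2.0 * x)
        assert p < 1e-12

    def test_df_matches_study_shape(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 175, 44)
        y = 0.5 + 0.002 * x + rng.normal(0, 0.1, 44)
        fit = fit_relation(x, y, "linear")
        assert fit.df == 42

    def test_matches_statsmodels_ols(self):
        """t, df and p agree with an independent OLS implementation."""
        rng = np.random.default_rng(21)
        x = rng.uniform(1, 175, 30)
        y = 0.2 + 0.003 * x + rng.normal(0, 0.05, 30)
        for relation in ("linear", "square", "logarithmic"):
            g = relation_transform(relation, x)
            res = sm.OLS(y, sm.add_constant(g)).fit()
            fit = fit_relation(x, y, relation, parameter="p")
            assert fit.t_stat == pytest.approx(res.tvalues[1], abs=1e-8)
            assert fit.p_value == pytest.approx(res.pvalues[1], abs=1e-10)
            assert fit.df == res.df_resid
            assert fit.r_squared == pytest.approx(res.rsquared, abs=1e-10)
            t, df, p = wald_slope_test(fit, x, y)
            assert (t, df, p) == (fit.t_stat, fit.df, fit.p_value)

    def test_zero_variance_regressor_rejected(self):
        with pytest.raises(ValueError):
            wald_slope_test_xy(np.full(5, 2.0), np.arange(5.0))


class TestSelectBest:
    def _fit(self, relation, rss, r2):
        return RelationFit(parameter="p", side_role=None, relation=relation,
                           beta0=0, beta1=1, r_squared=r2, t_stat=3.0, df=10,
                           p_value=0.01, fit_error=rss, n=12)

    def test_lowest_error_wins(self):
        best = select_best([self._fit("linear", 3.0, 0.5),
                            self._fit("logarithmic", 2.0, 0.4)])
        assert best.relation == "logarithmic"

    def test_tie_broken_by_r_squared(self):
        best = select_best([self._fit("linear", 2.0, 0.5),
                            self._fit("square", 2.0, 0.6)])
        assert best.relation == "square"

    def test_empty_means_no_result(self):
        assert select_best([]) is None


class TestRegularRatioRegression:
    def test_recovers_noise_free_log_linear_model(self):
        """Ratios following exp(-3.18 + 0.02 d) are recovered exactly."""
        d = np.array([3.0, 20.0, 45.0, 80.0, 120.0, 158.0])
        ratios = np.exp(-3.18 + 0.02 * d)
        fit = regular_ratio_regression(d, ratios)
        assert fit.beta1 == pytest.approx(0.02, abs=1e-9)
        assert fit.beta0 == pytest.approx(-3.18, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_ratios_give_zero_slope(self):
        d = np.array([3.0, 40.0, 90.0, 150.0])
        fit = regular_ratio_regression(d, np.full(4, 0.5))
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == pytest.approx(1.0)

    def test_zero_policy(self):
        d = np.array([3.0, 40.0, 90.0, 150.0])
        r = np.array([0.0, 0.2, 0.5, 0.9])
        fit = regular_ratio_regression(d, r)  # zero excluded
        assert fit.n == 3
        fit_eps = regular_ratio_regression(d, r, zero_policy="epsilon")
        assert fit_eps.n == 4
        with pytest.raises(ValueError):
            regular_ratio_regression(d[:3], np.zeros(3))


class TestRecoveryTrendModel:
    def _table(self):
        rng = np.random.default_rng(8)
        rows = []
        for subj in range(6):
            for d in (5, 42, 90, 160):
                for role in ("injured", "healthy"):
                    base = {name: np.nan for name in PARAMETER_NAMES}
                    trend = 0.004 * d if role == "injured" else 0.001 * d
                    base.update({
                        "subject_id": f"S{subj}",
                        "side_role": role,
                        "days_after_surgery": d,
                        "n_strides": 10,
                        "regular_ratio": min(1.0, np.exp(-3.0 + 0.018 * d)),
                        "F_mean_TP": 60 + 100 * trend + rng.normal(0, 2),
                        "F_total_max": 80 + 120 * trend + rng.normal(0, 3),
                    })
                    rows.append(base)
        return pd.DataFrame(rows)

    def test_fit_returns_significant_positive_trends(self):
        res = RecoveryTrendModel(self._table()).fit()
        f = res.best_fits[("F_mean_TP", "injured")]
        assert f is not None and f.beta1 > 0 and f.p_value < 0.05
        assert res.best_fits[("Time_inter_TP", "injured")] is None

    def test_summary_lists_ratio_models(self):
        res = RecoveryTrendModel(self._table()).fit()
        text = res.summary()
        assert "log(regular_ratio_healthy)" in text
        assert "F_mean_TP" in text

    def test_to_frame_matches_best_fits(self):
        res = RecoveryTrendModel(self._table()).fit()
        frame = res.to_frame()
        n_best = sum(1 for f in res.best_fits.values() if f is not None)
        assert len(frame) == n_best
        assert set(frame["side"]) <= {"injured", "healthy"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="required columns"):
            RecoveryTrendModel(pd.DataFrame({"subject_id": []}))
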