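"""Preparation pipeline: winsorization, power transforms, standardization,
kNN imputation, covariate residualisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phenoclust.prep import (
    TASK_COLUMNS,
    TransformSpec,
    apply_power_transform,
    covariate_adjust,
    fit_power_transform,
    knn_impute,
    prepare_task_matrix,
    standardize,
    winsorize,
    _profile_negloglik,
)


class TestWinsorize:
    def test_interior_values_pass_through(self):
        x = np.array([5.0, 5.1, 5.2, 5.05, 4.9, 5.0, 5.15, 4.95])
        out = winsorize(x, coverage=0.5)
        # values strictly inside the quantile band are untouched
        lo, hi = np.quantile(x, [0.25, 0.75])
        inside = (x > lo) & (x < hi)
        assert np.array_equal(out[inside], x[inside])

    def test_infinity_replaced_by_upper_quantile_bound(self):
        # {1..40, +inf}: the sentinel becomes max+1=41, and the type-7
        # 97.5th percentile of the 41 values is exactly 40.
        x = np.concatenate([np.arange(1.0, 41.0), [np.inf]])
        out = winsorize(x)
        assert out[-1] == pytest.approx(40.0)
        assert np.isfinite(out).all()
        # the same convention clips the minimum to the 2.5% bound (= 2.0)
        assert out[0] == pytest.approx(2.0)
        assert np.allclose(out[1:-1], x[1:-1], rtol=0, atol=1e-9)

    def test_constant_vector_unchanged(self):
        out = winsorize(np.full(10, 3.3))
        assert np.array_equal(out, np.full(10, 3.3))

    def test_neg_infinity_goes_to_lower_bound(self):
        x = np.concatenate([[-np.inf], np.arange(1.0, 41.0)])
        out = winsorize(x)
        assert out[0] == pytest.approx(np.quantile(np.concatenate([[0.0], np.arange(1.0, 41.0)]), 0.025))

    def test_rejects_bad_coverage_and_too_few_finite(self):
        with pytest.raises(ValueError):
            winsorize([1.0, 2.0, 3.0], coverage=1.5)
        with pytest.raises(ValueError):
            winsorize([1.0, np.inf, np.inf])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40, unique=True))
    def test_rank_order_of_finite_values_preserved(self, vals):
        x = np.asarray(vals)
        out = winsorize(x)
        order_in = np.argsort(x, kind="stable")
        assert np.all(np.diff(out[order_in]) >= 0)


class TestPowerTransform:
    def test_yeo_johnson_lambda_1_is_identity(self):
        x = np.array([-3.0, -0.5, 0.0, 1.2, 7.0])
        spec = TransformSpec(name="v", family="yeo_johnson", lmbda=1.0)
        assert np.allclose(apply_power_transform(x, spec), x)

    def test_lognormal_recovers_log_lambda(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 1, 500))
        spec = fit_power_transform(x)
        assert spec.family == "box_cox"
        assert abs(spec.lmbda) < 0.15

    def test_optimizer_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, 3.0, 200)
        spec = fit_power_transform(x)
        grid = np.arange(-2.0, 2.0 + 1e-9, 1e-3)
        lls = [-_profile_negloglik(l, x, None, "box_cox") for l in grid]
        assert abs(spec.lmbda - grid[int(np.argmax(lls))]) < 2e-3

    def test_matches_scipy_boxcox_mle_intercept_only(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(1.0, 0.7, 300)
        spec = fit_power_transform(x)
        lm_scipy = stats.boxcox_normmax(x, brack=(-2, 2), method="mle")
        assert spec.lmbda == pytest.approx(float(lm_scipy), abs=5e-3)

    def test_box_cox_rejected_for_nonpositive(self):
        with pytest.raises(ValueError):
            fit_power_transform(np.linspace(-1, 5, 30), family="box_cox")

    def test_infinite_input_rejected(self):
        x = np.r_[np.ones(20), np.inf]
        with pytest.raises(ValueError):
            fit_power_transform(x)


class TestStandardize:
    def test_two_point_column(self):
        # {0,2}: mean 1, sample SD (n-1 denominator) = sqrt(2)
        out = standardize(np.array([[0.0], [2.0]]))
        assert np.allclose(out.values.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert out.specs[0].center == pytest.approx(1.0)
        assert out.specs[0].scale == pytest.approx(np.sqrt(2))

    def test_already_standardized_unchanged(self, rng):
        x = rng.normal(0, 1, 200)
        x = (x - x.mean()) / x.std(ddof=1)
        out = standardize(x[:, None])
        assert np.allclose(out.values.ravel(), x, atol=1e-12)

    def test_missing_cells_ignored_in_moments(self):
        col = np.array([1.0, 2.0, 3.0, np.nan])
        out = standardize(col[:, None])
        obs = out.values[:3, 0]
        assert abs(obs.mean()) < 1e-10
        assert abs(obs.std(ddof=1) - 1) < 1e-10
        assert np.isnan(out.values[3, 0])

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            standardize(np.ones((5, 1)))


class TestKnnImpute:
    def test_no_missing_is_identity(self, rng):
        M = rng.normal(0, 1, (10, 4))
        assert np.array_equal(knn_impute(M), M)

    def test_unanimous_neighbours(self):
        M = np.array(
            [[0.0, 7.0], [0.1, 7.0], [0.2, 7.0], [0.3, 7.0], [0.4, 7.0], [0.0, np.nan]]
        )
        out = knn_impute(M, k=5)
        assert out[5, 1] == pytest.approx(7.0)

    def test_exp_distance_kernel_hand_computed(self):
        # two neighbours at distances 1 and 3 with values 0 and 10:
        # imputed = 10*exp(-3) / (exp(-1) + exp(-3))
        M = np.array([[1.0, 0.0], [3.0, 10.0], [0.0, np.nan]])
        out = knn_impute(M, k=2)
        expected = 10 * np.exp(-3) / (np.exp(-1) + np.exp(-3))
        assert out[2, 1] == pytest.approx(expected, abs=1e-12)

    def test_requires_complete_rows(self):
        M = np.array([[np.nan, 1.0], [2.0, np.nan]])
        with pytest.raises(ValueError):
            knn_impute(M)


class TestCovariateAdjust:
    def _table(self, n=200, beta_age_sz=0.0, seed=0):
        rng = np.random.default_rng(seed)
        dx = np.repeat(["SZ", "HC"], n // 2)
        age = rng.uniform(20, 55, n)
        t = pd.DataFrame({"participant_id": range(n), "diagnosis": dx, "age": age})
        for c in TASK_COLUMNS:
            # multiplicative age effect through the origin, so the truth is
            # consistent with the common-intercept interaction design
            base = np.exp(rng.normal(1.0, 0.5, n))
            base[dx == "SZ"] *= np.exp(beta_age_sz * age[dx == "SZ"] / 10)
            t[c] = base
        return t

    def test_empty_covariate_list_equals_unadjusted(self):
        t = self._table()
        a = covariate_adjust(t, [])
        b = prepare_task_matrix(t)
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_zero_effect_covariate_residuals_close_to_unadjusted(self):
        t = self._table(beta_age_sz=0.0, seed=1)
        adj = covariate_adjust(t, ["age"])
        raw = prepare_task_matrix(t)
        # with no true slope the adjusted matrix differs only by noise fitting
        corr = [
            np.corrcoef(adj.values[:, j], raw.values[:, j])[0, 1]
            for j in range(len(TASK_COLUMNS))
        ]
        assert min(corr) > 0.98

    def test_planted_sz_slope_removed(self):
        t = self._table(n=500, beta_age_sz=0.8, seed=2)
        adj = covariate_adjust(t, ["age"])
        sz = (t["diagnosis"] == "SZ").to_numpy()
        age_sz = t.loc[sz, "age"].to_numpy()
        worst = max(
            abs(np.corrcoef(adj.values[sz, j], age_sz)[0, 1])
            for j in range(len(TASK_COLUMNS))
        )
        assert worst < 0.05

    def test_sz_only_covariate_gives_hc_no_leverage(self):
        t = self._table(seed=3)
        t["cpz"] = np.where(t["diagnosis"] == "SZ", np.exp(6 + 0.3 * np.random.default_rng(4).normal(0, 1, len(t))), np.nan)
        adj = covariate_adjust(t, ["cpz"])
        # HC rows of the zero-filled covariate: residuals = transformed value
        # minus intercept fit, i.e. the HC block matches an HC-only centering
        assert adj.values.shape == (len(t), len(TASK_COLUMNS))
        assert adj.adjusted

    def test_missing_covariate_column_errors(self, default_cohort):
        table, _ = default_cohort
        with pytest.raises(ValueError):
            covariate_adjust(table, ["nonexistent_covariate"])


class TestPreparedInvariants:
    def test_columns_standardized_over_observed(self, prepared_default):
        V = prepared_default.values
        for j in range(V.shape[1]):
            col = V[:, j]
            obs = col[~np.isnan(col)]
            assert abs(obs.mean()) < 1e-10
            assert abs(obs.std(ddof=1) - 1.0) < 1e-10

    def test_refit_on_own_output_is_idempotent(self, prepared_default):
        V = prepared_default.values.copy()
        out = standardize(V, columns=prepared_default.columns)
        assert np.allclose(out.values, V, atol=1e-10, equal_nan=True)
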