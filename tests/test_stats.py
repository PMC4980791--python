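"""Group tests, meta-analysis closed forms, covariate and outcome models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epiaccel import (
    fit_accel_covariate_model,
    fit_outcome_model,
    fixed_effects_meta,
    group_mean_diff_z,
    group_test,
    stouffer_meta,
)


class TestGroupTest:
    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        g = np.repeat(["a", "b"], 30)
        comp = group_test(x, g, method="anova")
        t = sps.ttest_ind(x[g == "a"], x[g == "b"]).statistic
        assert comp.statistic == pytest.approx(t**2, abs=1e-9)

    def test_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 90)
        g = rng.choice(["a", "b", "c"], 90)
        perm = rng.permutation(90)
        for method in ("anova", "kruskal"):
            c1 = group_test(x, g, method=method)
            c2 = group_test(x[perm], g[perm], method=method)
            assert c1.statistic == pytest.approx(c2.statistic)
            assert c1.p_value == pytest.approx(c2.p_value)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        g = np.repeat(["a", "b"], 50)
        assert group_test(x, g, "anova").p_value < 1e-6
        assert group_test(x, g, "kruskal").p_value < 1e-6

    def test_group_table_bar_plot_contract(self):
        x = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        g = np.repeat(["a", "b"], 3)
        comp = group_test(x, g)
        assert comp.groups.loc["a", "n"] == 3
        assert comp.groups.loc["b", "mean"] == pytest.approx(8.0)
        assert comp.groups.loc["b", "se"] == pytest.approx(1.0 / np.sqrt(3))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            group_test([1.0, 2.0], ["a", "a"])


class TestStouffer:
    def test_single_study_identity(self):
        res = stouffer_meta([1.96])
        assert res.estimate == pytest.approx(1.96, abs=1e-12)

    def test_two_equal_studies(self):
        z = 1.5
        res = stouffer_meta([z, z])
        assert res.estimate == pytest.approx(z * np.sqrt(2), abs=1e-12)

    def test_three_equal_studies_closed_form(self):
        res = stouffer_meta([1.2816] * 3)
        assert res.estimate == pytest.approx(1.2816 * np.sqrt(3), abs=1e-12)
        expected_p = 2 * sps.norm.sf(1.2816 * np.sqrt(3))
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_monotone_in_study_count(self):
        vals = [stouffer_meta([1.0] * k).estimate for k in range(1, 8)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_weighted_combination(self):
        res = stouffer_meta([2.0, 0.0], weights=[3.0, 1.0])
        assert res.estimate == pytest.approx(6.0 / np.sqrt(10.0), abs=1e-12)

    def test_empty_and_bad_weights(self):
        with pytest.raises(ValueError):
            stouffer_meta([])
        with pytest.raises(ValueError):
            stouffer_meta([1.0], weights=[0.0])


class TestFixedEffects:
    def test_single_study_identity(self):
        res = fixed_effects_meta([1.3], [0.4])
        assert res.estimate == pytest.approx(1.3)
        assert res.se == pytest.approx(0.4)

    def test_identical_studies_shrink_se(self):
        k = 4
        res = fixed_effects_meta([2.0] * k, [0.8] * k)
        assert res.estimate == pytest.approx(2.0, abs=1e-12)
        assert res.se == pytest.approx(0.8 / np.sqrt(k), abs=1e-12)

    def test_equal_se_studies_average(self):
        res = fixed_effects_meta([1.0, 3.0], [1.0, 1.0])
        assert res.estimate == pytest.approx(2.0, abs=1e-12)
        assert res.se == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_pooled_within_study_range_and_ci_contains_estimate(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0, 2, 6)
        se = rng.uniform(0.2, 1.5, 6)
        res = fixed_effects_meta(d, se)
        assert d.min() <= res.estimate <= d.max()
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_meta([1.0], [0.0])


def test_group_mean_diff_sign_convention():
    x = np.array([0.0, 0.0, 1.0, 1.0])
    g = np.array(["a", "a", "b", "b"])
    d, se, z = group_mean_diff_z(x + [0, 0.1, 0, 0.1], g, ("a", "b"))
    assert d == pytest.approx(1.0)
    d2, _, _ = group_mean_diff_z(x + [0, 0.1, 0, 0.1], g, ("b", "a"))
    assert d2 == pytest.approx(-1.0)


class TestCovariateModel:
    def test_recovers_known_coefficient(self):
        rng = np.random.default_rng(4)
        n = 500
        x = rng.normal(0, 1, n)
        accel = 2.0 * x + rng.normal(0, 0.1, n)
        tab = fit_accel_covariate_model(accel, pd.DataFrame({"x": x}))
        assert 1.95 <= tab.loc["x", "estimate"] <= 2.05
        assert tab.attrs["r_squared"] > 0.99

    def test_categorical_expanded_against_reference_level(self):
        rng = np.random.default_rng(5)
        n = 300
        g = rng.choice(["ctl", "trt"], n)
        accel = 1.0 * (g == "trt") + rng.normal(0, 0.2, n)
        tab = fit_accel_covariate_model(accel, pd.DataFrame({"group": g}))
        assert "group[trt]" in tab.index
        assert tab.loc["group[trt]", "estimate"] == pytest.approx(1.0, abs=0.1)

    def test_constant_covariate_dropped_without_effect(self):
        rng = np.random.default_rng(6)
        n = 200
        x = rng.normal(0, 1, n)
        accel = x + rng.normal(0, 0.5, n)
        t1 = fit_accel_covariate_model(accel, pd.DataFrame({"x": x}))
        t2 = fit_accel_covariate_model(
            accel, pd.DataFrame({"x": x, "zero": np.zeros(n)})
        )
        assert "zero" not in t2.index
        assert t2.loc["x", "estimate"] == pytest.approx(t1.loc["x", "estimate"])

    def test_null_covariate_p_roughly_uniform(self):
        """Type-I error of the covariate t-test sits near the nominal 5%."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(0, 1, 60)
            accel = rng.normal(0, 1, 60)
            tab = fit_accel_covariate_model(accel, pd.DataFrame({"x": x}))
            hits += tab.loc["x", "p"] < 0.05
        assert 0.02 <= hits / reps <= 0.08


class TestOutcomeModel:
    def _simulate(self, beta, n, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        p = 1.0 / (1.0 + np.exp(-(0.2 + beta * x)))
        y = (rng.random(n) < p).astype(float)
        return y, x

    def test_recovers_log_odds_coefficient(self):
        y, x = self._simulate(0.5, 2000, seed=1)
        tab = fit_outcome_model(y, x)
        assert tab.loc["accel", "estimate"] == pytest.approx(0.5, abs=0.1)

    def test_label_swap_negates_estimates(self):
        y, x = self._simulate(0.8, 500, seed=2)
        t1 = fit_outcome_model(y, x)
        t2 = fit_outcome_model(1 - y, x)
        np.testing.assert_allclose(t1["estimate"], -t2["estimate"], atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_outcome_model(np.ones(50), np.random.default_rng(3).normal(0, 1, 50))

    def test_complete_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            fit_outcome_model(y, x)
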