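"""Age transform, elastic-net clock, spline age-acceleration residual."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiaccel import (
    SimConfig,
    inverse_transform_age,
    predict_dnam_age,
    simulate_cohort,
    train_clock,
    transform_age,
    universal_age_accel,
)


class TestAgeTransform:
    def test_zero_at_adult_age(self):
        assert transform_age(20.0, 20.0) == pytest.approx(0.0)

    def test_linear_branch_value(self):
        # one adult-age unit above the knot: (41 - 20) / 21 = 1
        assert transform_age(41.0, 20.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("age", [0.0, 1.0, 19.0, 20.0, 21.0, 80.0])
    def test_inverse_contract(self, age):
        assert inverse_transform_age(transform_age(age)) == pytest.approx(age, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(age=st.floats(-0.99, 120.0))
    def test_strictly_increasing_and_invertible(self, age):
        eps = 1e-4
        assert transform_age(age + eps) > transform_age(age)
        assert inverse_transform_age(transform_age(age)) == pytest.approx(age, abs=1e-9)

    def test_rejects_age_below_minus_one(self):
        with pytest.raises(ValueError):
            transform_age(-1.0)


def _training_cohort(**kw):
    cfg = SimConfig(n_samples=kw.pop("n", 200), age_range=(40.0, 90.0),
                    seed=kw.pop("seed", 11), probe_seed=777, **kw)
    beta, ann, truth = simulate_cohort(cfg)
    non_sig = truth.probes.index[truth.probes["class"] != "signature"]
    return beta.loc[non_sig], ann["age"], truth


class TestTrainClock:
    def test_deterministic(self):
        beta, ages, _ = _training_cohort()
        m1 = train_clock(beta, ages, seed=3)
        m2 = train_clock(beta, ages, seed=3)
        pd.testing.assert_series_equal(m1.coefficients, m2.coefficients)
        assert m1.intercept == m2.intercept

    def test_zero_variance_probe_gets_zero_coefficient(self):
        beta, ages, _ = _training_cohort()
        beta = beta.copy()
        beta.loc["cg_flat"] = 0.5
        model = train_clock(beta, ages, seed=3)
        assert model.coefficients.loc["cg_flat"] == 0.0

    def test_noiseless_cohort_nearly_perfect_heldout(self):
        """With no measurement noise and no intrinsic scatter the held-out
        DNAm age correlates >= 0.99 with chronological age."""
        kw = dict(measurement_sd=0.0, intrinsic_sd_years=0.0, sex_effect_years=0.0)
        beta, ages, truth = _training_cohort(n=300, **kw)
        model = train_clock(beta, ages, seed=0)
        # share the probe universe with the training run
        test_cfg = replace(SimConfig(n_samples=100, age_range=(40.0, 90.0), **kw),
                           probe_seed=truth.config.probe_seed, seed=77)
        tb, ta, _ = simulate_cohort(test_cfg)
        pred = predict_dnam_age(model, tb)
        assert np.corrcoef(pred, ta["age"])[0, 1] >= 0.99

    def test_constant_ages_rejected(self):
        beta, ages, _ = _training_cohort()
        with pytest.raises(ValueError, match="constant"):
            train_clock(beta, np.full(len(ages), 50.0))

    def test_too_few_samples_rejected(self):
        beta, ages, _ = _training_cohort()
        with pytest.raises(ValueError, match="50"):
            train_clock(beta.iloc[:, :30], ages[:30])


class TestPredict:
    def test_training_mean_input_gives_constant_prediction(self, models):
        clock = models.clock
        probes = clock.clock_probes
        data = pd.concat([clock.training_means.loc[probes]] * 3, axis=1)
        data.columns = ["a", "b", "c"]
        pred = predict_dnam_age(clock, data)
        assert pred.nunique() == 1
        expected = inverse_transform_age(
            clock.intercept
            + clock.training_means.loc[probes] @ clock.coefficients.loc[probes],
            clock.adult_age,
        )
        assert pred.iloc[0] == pytest.approx(expected)

    def test_missing_clock_probe_raises(self, models, default_cohort):
        beta, _, _ = default_cohort
        probe = models.clock.clock_probes[0]
        with pytest.raises(ValueError, match="impute"):
            predict_dnam_age(models.clock, beta.drop(index=probe))

    def test_default_noise_heldout_correlation(self, models, default_cohort):
        beta, ann, _ = default_cohort
        pred = predict_dnam_age(models.clock, beta)
        assert np.corrcoef(pred, ann["age"])[0, 1] >= 0.85


class TestUniversalAgeAccel:
    def _fixture(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(50, 80, n)
        dnam = pd.Series(age + rng.normal(0, 3, n),
                         index=[f"s{i}" for i in range(n)], name="dnam_age")
        ann = pd.DataFrame(
            {"group": np.where(rng.random(n) < 0.6, "ref", "other"), "age": age},
            index=dnam.index,
        )
        return dnam, age, ann

    def test_reference_group_mean_is_zero(self):
        dnam, age, ann = self._fixture()
        accel, _ = universal_age_accel(dnam, age, ann, "ref")
        assert abs(accel[ann["group"] == "ref"].mean()) < 1e-6

    def test_points_on_spline_have_zero_accel(self):
        dnam, age, ann = self._fixture()
        _, fit = universal_age_accel(dnam, age, ann, "ref")
        on_curve = pd.Series(fit.predict(age), index=dnam.index)
        accel, _ = universal_age_accel(on_curve, age, ann, "ref")
        # the refit reproduces the same curve, so residuals vanish
        np.testing.assert_allclose(accel.to_numpy(), 0.0, atol=1e-8)

    def test_residual_linearity_for_nonreference_sample(self):
        dnam, age, ann = self._fixture()
        accel, _ = universal_age_accel(dnam, age, ann, "ref")
        bumped = dnam.copy()
        target = ann.index[ann["group"] == "other"][0]
        bumped.loc[target] += 5.0
        accel2, _ = universal_age_accel(bumped, age, ann, "ref")
        assert accel2.loc[target] - accel.loc[target] == pytest.approx(5.0, abs=1e-9)
        others = ann.index.drop(target)
        np.testing.assert_allclose(accel2.loc[others], accel.loc[others], atol=1e-9)

    def test_constant_shift_of_all_samples_leaves_accel_unchanged(self):
        dnam, age, ann = self._fixture()
        a1, _ = universal_age_accel(dnam, age, ann, "ref")
        a2, _ = universal_age_accel(dnam + 7.5, age, ann, "ref")
        np.testing.assert_allclose(a1.to_numpy(), a2.to_numpy(), atol=1e-8)

    def test_small_reference_group_falls_back_to_linear(self):
        dnam, age, ann = self._fixture(n=40)
        ann["group"] = ["ref"] * 15 + ["other"] * 25
        _, fit = universal_age_accel(dnam, age, ann, "ref")
        assert fit.knots is None and fit.df == 1

    def test_missing_reference_label_raises(self):
        dnam, age, ann = self._fixture()
        with pytest.raises(ValueError, match="absent"):
            universal_age_accel(dnam, age, ann, "nope")
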