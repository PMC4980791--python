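"""IEAA regression, Klemera-Doubal composite, EEAA residual."""

import numpy as np
import pandas as pd
import pytest

from epiaccel import (
    KDModel,
    compute_eeaa,
    compute_ieaa,
    fit_kd_model,
    kd_composite_age,
)


def _cells(n, rng):
    return pd.DataFrame(
        {
            "naiveCD8T": rng.uniform(0.02, 0.1, n),
            "exhCD8T": rng.uniform(0.5, 15.0, n),
            "plasmablast": rng.uniform(0.001, 0.03, n),
            "CD4T": rng.uniform(0.1, 0.2, n),
            "NK": rng.uniform(0.03, 0.1, n),
            "mono": rng.uniform(0.05, 0.12, n),
            "gran": rng.uniform(0.4, 0.7, n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestIEAA:
    def test_orthogonal_to_age_and_every_cell_covariate(self):
        rng = np.random.default_rng(0)
        n = 300
        cells = _cells(n, rng)
        age = rng.uniform(50, 80, n)
        dnam = pd.Series(age + rng.normal(0, 4, n), index=cells.index)
        ieaa, _ = compute_ieaa(dnam, age, cells)
        assert abs(np.corrcoef(ieaa, age)[0, 1]) < 1e-8
        for c in cells.columns:
            assert abs(np.corrcoef(ieaa, cells[c])[0, 1]) < 1e-8
        assert abs(ieaa.mean()) < 1e-9

    def test_exact_linear_function_leaves_zero_residual(self):
        rng = np.random.default_rng(1)
        n = 100
        cells = _cells(n, rng)
        age = rng.uniform(50, 80, n)
        dnam = pd.Series(2.0 + 0.9 * age + 3.0 * cells["naiveCD8T"]
                         - 0.5 * cells["gran"], index=cells.index)
        ieaa, _ = compute_ieaa(dnam, age, cells)
        np.testing.assert_allclose(ieaa.to_numpy(), 0.0, atol=1e-9)

    def test_constant_shift_absorbed_by_intercept(self):
        rng = np.random.default_rng(2)
        n = 120
        cells = _cells(n, rng)
        age = rng.uniform(50, 80, n)
        dnam = pd.Series(age + rng.normal(0, 3, n), index=cells.index)
        i1, _ = compute_ieaa(dnam, age, cells)
        i2, _ = compute_ieaa(dnam + 11.0, age, cells)
        np.testing.assert_allclose(i1.to_numpy(), i2.to_numpy(), atol=1e-9)

    def test_missing_covariate_column_raises(self):
        rng = np.random.default_rng(3)
        cells = _cells(50, rng).drop(columns="NK")
        age = rng.uniform(50, 80, 50)
        dnam = pd.Series(age, index=cells.index)
        with pytest.raises(KeyError, match="NK"):
            compute_ieaa(dnam, age, cells)


class TestKDModel:
    def test_recovers_linear_marker_with_noise(self):
        rng = np.random.default_rng(4)
        n = 500
        age = rng.uniform(30, 90, n)
        markers = pd.DataFrame({"m": 2.0 * age + 5.0 + rng.normal(0, 1, n)})
        model = fit_kd_model(markers, age)
        row = model.params.loc["m"]
        assert 1.9 <= row["k"] <= 2.1
        assert 3.0 <= row["q"] <= 7.0
        assert row["s"] == pytest.approx(1.0, abs=0.15)

    def test_exact_linear_marker_hits_s_floor(self):
        age = np.linspace(30, 90, 50)
        markers = pd.DataFrame({"m": 2.0 * age + 5.0})
        model = fit_kd_model(markers, age)
        assert model.params.loc["m", "s"] == pytest.approx(1e-6 * 2.0, rel=1e-6)

    def test_age_independent_marker_usually_screened_out(self):
        excluded = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            age = rng.uniform(30, 90, 200)
            markers = pd.DataFrame({"null": rng.normal(0, 1, 200),
                                    "real": age + rng.normal(0, 5, 200)})
            model = fit_kd_model(markers, age)
            excluded += "null" in model.excluded
        assert excluded >= 18

    def test_refit_identical(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(30, 90, 100)
        markers = pd.DataFrame({"m": age + rng.normal(0, 2, 100)})
        p1 = fit_kd_model(markers, age).params
        p2 = fit_kd_model(markers, age).params
        pd.testing.assert_frame_equal(p1, p2)

    def test_constant_marker_raises(self):
        age = np.linspace(30, 90, 50)
        with pytest.raises(ValueError, match="constant"):
            fit_kd_model(pd.DataFrame({"m": np.ones(50)}), age)


class TestKDComposite:
    def _model(self, rows):
        return KDModel(params=pd.DataFrame(rows, index=["k", "q", "s"]).T,
                       excluded=[], meta={})

    def test_single_marker_reduces_to_inverse_regression(self):
        model = self._model({"m": [1.0, 0.0, 2.0]})
        markers = pd.DataFrame({"m": [50.0, 30.0]})
        ba = kd_composite_age(model, markers)
        np.testing.assert_allclose(ba.to_numpy(), [50.0, 30.0])

    def test_equal_weight_markers_average(self):
        model = self._model({"a": [2.0, 1.0, 3.0], "b": [2.0, 5.0, 3.0]})
        markers = pd.DataFrame({"a": [21.0], "b": [25.0]})
        ba = kd_composite_age(model, markers)
        expected = 0.5 * ((21.0 - 1.0) / 2.0 + (25.0 - 5.0) / 2.0)
        assert ba.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_noiseless_linear_panel_returns_age_exactly(self):
        """Markers that are exact linear functions of age reproduce age."""
        age = np.linspace(40, 85, 60)
        markers = pd.DataFrame({
            "a": 1.5 * age + 2.0,
            "b": -0.7 * age + 90.0,
            "c": 0.01 * age + 0.2,
        })
        model = fit_kd_model(markers, age)
        ba = kd_composite_age(model, markers)
        np.testing.assert_allclose(ba.to_numpy(), age, atol=1e-9)

    def test_missing_marker_raises(self):
        model = self._model({"m": [1.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            kd_composite_age(model, pd.DataFrame({"other": [1.0]}))


class TestEEAA:
    def test_orthogonal_to_age_and_mean_zero(self):
        rng = np.random.default_rng(6)
        age = rng.uniform(50, 80, 200)
        comp = pd.Series(age + rng.normal(0, 3, 200))
        eeaa = compute_eeaa(comp, age)
        assert abs(np.corrcoef(eeaa, age)[0, 1]) < 1e-8
        assert abs(eeaa.sum()) < 1e-9

    def test_linear_composite_gives_zero(self):
        age = np.linspace(50, 80, 50)
        eeaa = compute_eeaa(pd.Series(0.8 * age + 4.0), age)
        np.testing.assert_allclose(eeaa.to_numpy(), 0.0, atol=1e-10)

    def test_sign_contract_on_default_cohort(self, analyzed):
        """EEAA correlates positively with the exhausted-CD8 score and
        negatively with the naive-CD8 score — the immunosenescence
        direction is built into the composite."""
        eeaa = analyzed["accel"].eeaa
        adv = analyzed["counts"].advanced
        assert np.corrcoef(eeaa, adv["exhCD8T"])[0, 1] > 0
        assert np.corrcoef(eeaa, adv["naiveCD8T"])[0, 1] < 0

    def test_moderate_correlation_with_ieaa(self, analyzed):
        r = np.corrcoef(analyzed["accel"].ieaa, analyzed["accel"].eeaa)[0, 1]
        assert 0.2 < r < 0.95

    def test_all_three_measures_age_uncorrelated_and_centered(self, analyzed):
        accel = analyzed["accel"]
        age = analyzed["annotation"]["age"]
        for v in (accel.ieaa, accel.eeaa):
            assert abs(np.corrcoef(v, age)[0, 1]) < 1e-6
            assert abs(v.mean()) < 1e-9
        ref = analyzed["annotation"]["group"] == "A"
        assert abs(accel.age_accel[ref].mean()) < 1e-6
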