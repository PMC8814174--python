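import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from movemeta.effect_sizes import ConversionError
from movemeta.range_regression import (climate_rate_regression,
                                       compute_range_effects,
                                       dispersal_rate,
                                       divergence_time_regression, lnrr,
                                       lnrr_variance, sd_from_ci, sd_from_se)
from movemeta.synthetic import SyntheticTruth, simulate_range_dataset

positive = st.floats(0.1, 50.0)


class TestLnRR:
    def test_equal_means_zero(self):
        assert lnrr(3.2, 3.2) == 0.0

    def test_doubling(self):
        assert lnrr(2.0, 1.0) == pytest.approx(math.log(2), abs=1e-12)

    @given(positive, positive)
    def test_antisymmetry(self, a, b):
        assert lnrr(a, b) == pytest.approx(-lnrr(b, a), abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ConversionError):
            lnrr(0.0, 1.0)


class TestLnRRVariance:
    def test_hand_computed(self):
        v = lnrr_variance(0.4, 4, 2.0, 0.2, 4, 1.0)
        assert v == pytest.approx(0.02, abs=1e-15)   # 0.16/16 + 0.04/4

    def test_zero_sds(self):
        assert lnrr_variance(0.0, 5, 1.0, 0.0, 5, 2.0) == 0.0

    def test_mean_scaling(self):
        v1 = lnrr_variance(0.3, 6, 1.5, 0.2, 8, 0.9)
        v2 = lnrr_variance(0.3, 6, 3.0, 0.2, 8, 1.8)
        assert v2 == pytest.approx(v1 / 4)

    @given(positive, positive, st.floats(0.01, 5), st.floats(0.01, 5),
           st.integers(2, 50), st.integers(2, 50))
    @settings(max_examples=60)
    def test_against_numeric_delta_method(self, me, mc, se, sc, ne, nc):
        """Independent oracle: propagate group-mean variances through
        ln(me/mc) with numerically differentiated sensitivities."""
        h = 1e-6
        g_e = (math.log((me + h) / mc) - math.log((me - h) / mc)) / (2 * h)
        g_c = (math.log(me / (mc + h)) - math.log(me / (mc - h))) / (2 * h)
        oracle = g_e ** 2 * se ** 2 / ne + g_c ** 2 * sc ** 2 / nc
        assert lnrr_variance(se, ne, me, sc, nc, mc) == \
            pytest.approx(oracle, rel=1e-6)


class TestDispersalRate:
    def test_simple(self):
        assert dispersal_rate(100.0, 1950, 2000) == 2.0

    def test_zero_distance(self):
        assert dispersal_rate(0.0, 1950, 2000) == 0.0

    def test_year_shift_invariance(self):
        assert dispersal_rate(30, 1960, 1990) == dispersal_rate(30, 1760, 1790)

    def test_equal_years_rejected(self):
        with pytest.raises(ConversionError):
            dispersal_rate(10, 2000, 2000)


class TestConversions:
    def test_se_to_sd(self):
        assert sd_from_se(0.5, 16) == pytest.approx(2.0)

    def test_ci_to_sd(self):
        assert sd_from_ci(1.96, 25) == pytest.approx(5.0)


class TestComputeRangeEffects:
    def test_missing_year_rejected(self):
        raw, _ = simulate_range_dataset(SyntheticTruth(seed=1), k=10)
        raw.loc[0, "year_core_established"] = np.nan
        table = compute_range_effects(raw)
        assert len(table.effects) == 9
        assert table.rejections.iloc[0]["reason_code"] == "missing_year"

    def test_abs_lnrr_and_eff_n(self):
        raw, _ = simulate_range_dataset(SyntheticTruth(seed=2), k=30)
        table = compute_range_effects(raw)
        eff = table.effects
        np.testing.assert_array_equal(eff["abs_lnrr"], eff["lnrr"].abs())
        expected = np.sqrt((eff["n_core"] + eff["n_edge"])
                           / (eff["n_core"] * eff["n_edge"]))
        np.testing.assert_allclose(eff["sqrt_inv_eff_n"], expected)
        assert (eff["v_lnrr"] > 0).all()

    def test_se_rows_converted(self):
        raw, _ = simulate_range_dataset(SyntheticTruth(seed=3), k=20)
        se_rows = raw["se_core"].notna()
        assert se_rows.any()
        table = compute_range_effects(raw)
        assert len(table.effects) == 20 and table.rejections.empty


class TestClimateRegression:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        rows = []
        offsets = {"aerial": 3.0, "aquatic": 1.0, "terrestrial": 0.5}
        for i in range(60):
            mode = ("aerial", "aquatic", "terrestrial")[i % 3]
            dt = rng.normal(0, 2)
            rows.append({"dispersal_rate_km_y": 2.0 * dt + offsets[mode],
                         "delta_temp_C": dt, "dispersal_mode": mode})
        reg = climate_rate_regression(pd.DataFrame(rows))
        np.testing.assert_allclose(reg.slopes["estimate"], 2.0, atol=1e-10)
        for mode, off in offsets.items():
            assert reg.intercepts.loc[mode, "estimate"] == pytest.approx(off, abs=1e-10)

    def test_zero_variance_predictor_errors(self):
        df = pd.DataFrame({"dispersal_rate_km_y": [1, 2, 3, 4],
                           "delta_temp_C": [1.0] * 4,
                           "dispersal_mode": ["aerial"] * 4})
        with pytest.raises(ValueError, match="zero variance"):
            climate_rate_regression(df)

    def test_single_mode_drops_interaction(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "dispersal_rate_km_y": rng.normal(2, 1, 20),
            "delta_temp_C": rng.normal(0, 1, 20),
            "dispersal_mode": ["aquatic"] * 20})
        reg = climate_rate_regression(df)
        assert not reg.interaction
        assert list(reg.slopes.index) == ["aquatic"]

    def test_permuted_predictor_interval_contains_zero(self):
        truth = SyntheticTruth(seed=5)
        raw, _ = simulate_range_dataset(truth, k=200)
        eff = compute_range_effects(raw).effects
        hits = 0
        reps = 20
        for s in range(reps):
            perm = eff.assign(delta_temp_C=eff["delta_temp_C"]
                              .sample(frac=1, random_state=s).to_numpy())
            reg = climate_rate_regression(perm)
            hits += sum((reg.slopes["lower"] > 0) | (reg.slopes["upper"] < 0))
        # 3 modes x 20 permutations at ~5% each
        assert hits <= 0.1 * 3 * reps


class TestDivergenceRegression:
    def test_constant_magnitude_zero_slope(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"abs_lnrr": [0.4] * 30,
                           "time_diverged_y": rng.integers(5, 80, 30),
                           "dispersal_mode": ["aerial", "aquatic",
                                              "terrestrial"] * 10})
        reg = divergence_time_regression(df)
        np.testing.assert_allclose(reg.slopes["estimate"], 0.0, atol=1e-12)

    def test_sign_of_lnrr_irrelevant(self):
        raw, _ = simulate_range_dataset(SyntheticTruth(seed=6), k=90)
        eff = compute_range_effects(raw).effects
        a = divergence_time_regression(eff)
        flipped = eff.assign(lnrr=-eff["lnrr"], abs_lnrr=eff["abs_lnrr"])
        b = divergence_time_regression(flipped)
        pd.testing.assert_frame_equal(a.slopes, b.slopes)
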