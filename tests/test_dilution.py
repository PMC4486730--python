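import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinnicomp.dilution import (IVERSON_COEFFICIENT, StandardDilution,
                                WaterFatModel, adipose_and_fat_from_water_pr,
                                fat_from_water_iverson, fat_from_water_logit,
                                load_water_fat_config, proportion_water,
                                stock_specific_activity, tbw)


class TestStockActivity:
    def test_dilution_factor_arithmetic(self):
        std = StandardDilution(aliquot_ml=0.01, diluent_ml=1000.0,
                               activities_cpm_ml=[50.0])
        mean, sd = stock_specific_activity([std])
        assert mean == pytest.approx(50.0 * 1000.01 / 0.01)
        assert sd == 0.0

    def test_identical_replicates_zero_sd(self):
        std = StandardDilution(0.01, 1000.0, [40.0, 40.0])
        assert stock_specific_activity([std])[1] == 0.0

    def test_mean_of_back_computed_stocks(self):
        std = StandardDilution(0.01, 1000.0, [40.0, 60.0])
        mean, sd = stock_specific_activity([std])
        expect = np.mean([40 * 1000.01 / 0.01, 60 * 1000.01 / 0.01])
        assert mean == pytest.approx(expect)
        assert sd > 0

    def test_background_subtracted(self):
        with_bg = StandardDilution(0.01, 1000.0, [70.0], background_cpm_ml=20.0)
        no_bg = StandardDilution(0.01, 1000.0, [50.0])
        assert stock_specific_activity([with_bg]) == stock_specific_activity([no_bg])

    def test_nonpositive_net_raises(self):
        std = StandardDilution(0.01, 1000.0, [10.0], background_cpm_ml=20.0)
        with pytest.raises(ValueError):
            stock_specific_activity([std])


class TestTbw:
    @pytest.mark.parametrize("cpm_inj, eq, bg, expected", [
        (1e6, 100.0, 0.0, 10_000.0),
        (5e5, 60.0, 10.0, 10_000.0),
    ])
    def test_point_values(self, cpm_inj, eq, bg, expected):
        assert tbw(cpm_inj, eq, bg) == pytest.approx(expected)

    def test_no_signal_raises(self):
        with pytest.raises(ValueError):
            tbw(1e6, 50.0, 50.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), cpm=st.floats(1e4, 1e8),
           eq=st.floats(10.0, 1e4))
    def test_homogeneous_in_counts(self, scale, cpm, eq):
        """Scaling injected and net activities together leaves TBW fixed."""
        assert tbw(cpm * scale, eq * scale, 0.0) == pytest.approx(
            tbw(cpm, eq, 0.0), rel=1e-9)

    def test_proportion_water(self):
        assert proportion_water(240_000.0, 400.0) == pytest.approx(0.6)
        assert proportion_water(0.0, 400.0) == 0.0
        with pytest.raises(ValueError):
            proportion_water(400_000.0, 400.0)


class TestLogitModel:
    def model(self, a0=-1.6, a1=0.86, s2=0.09):
        return WaterFatModel("logit", {"alpha0": a0, "alpha1": a1, "sigma2": s2})

    def test_point_arithmetic(self):
        # x = 1 at P_H2O = 0.5: expit(-1.6 + 0.86)
        assert fat_from_water_logit(0.5, self.model()) == pytest.approx(0.323, abs=5e-4)

    def test_low_water_limit_is_intercept(self):
        out = fat_from_water_logit(1e-9, self.model())
        assert out == pytest.approx(1 / (1 + np.exp(1.6)), abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0.01, 0.99))
    def test_output_always_in_unit_interval(self, p):
        fitted = load_water_fat_config()["logit"]
        assert 0.0 < fat_from_water_logit(p, fitted) < 1.0

    def test_monotone_direction_follows_slope_sign(self):
        grid = np.linspace(0.2, 0.8, 13)
        decreasing = [fat_from_water_logit(p, self.model(a1=-1.6)) for p in grid]
        increasing = [fat_from_water_logit(p, self.model(a1=0.86)) for p in grid]
        assert np.all(np.diff(decreasing) < 0)
        assert np.all(np.diff(increasing) > 0)

    def test_boundary_raises(self):
        with pytest.raises(ValueError):
            fat_from_water_logit(0.0, self.model())

    def test_posterior_draws_propagate(self):
        draws = np.column_stack([np.full(100, 0.86), np.full(100, -1.6),
                                 np.full(100, 0.01)])
        m = WaterFatModel("logit", {}, draws=draws)
        out = fat_from_water_logit(0.5, m)
        assert out.shape == (100,)
        assert np.allclose(out, 1 / (1 + np.exp(-(0.86 - 1.6))))

    def test_predictive_noise_widens_with_water_ratio(self):
        rng = np.random.default_rng(0)
        draws = np.column_stack([np.full(4000, 0.86), np.full(4000, -1.6),
                                 np.full(4000, 0.09)])
        m = WaterFatModel("logit", {}, draws=draws)
        lo = fat_from_water_logit(0.3, m, rng=rng, predictive=True)
        hi = fat_from_water_logit(0.7, m, rng=rng, predictive=True)
        spread = lambda v: np.diff(np.percentile(np.log(v / (1 - v)), [2.5, 97.5]))
        assert spread(hi) > spread(lo)


class TestIverson:
    def test_printed_coefficient(self):
        p, neg = fat_from_water_iverson(0.5)
        assert p == pytest.approx(0.315)
        assert not neg

    def test_root_of_linear_rule(self):
        p, neg = fat_from_water_iverson(1.0 / IVERSON_COEFFICIENT)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_negative_flagged_not_clamped(self):
        p, neg = fat_from_water_iverson(0.8)
        assert p == pytest.approx(-0.096)
        assert neg


class TestPaceRathbun:
    def model(self, wa=0.2, wl=0.7, fa=0.854, adj=1.0):
        return WaterFatModel("pace_rathbun", {
            "w_adipose": (wa, 0.0), "w_lean": (wl, 0.0),
            "f_adipose": (fa, 0.0), "water_bias_adjustment": adj})

    def test_all_lean_limit(self):
        out = adipose_and_fat_from_water_pr(0.7, self.model())
        assert out["proportion_adipose"] == pytest.approx(0.0)

    def test_all_adipose_limit(self):
        out = adipose_and_fat_from_water_pr(0.2, self.model())
        assert out["proportion_adipose"] == pytest.approx(1.0)

    def test_midpoint(self):
        out = adipose_and_fat_from_water_pr(0.45, self.model())
        assert out["proportion_adipose"] == pytest.approx(0.5)
        assert out["proportion_fat"] == pytest.approx(0.5 * 0.854)

    def test_bias_adjustment_applied(self):
        raw = adipose_and_fat_from_water_pr(0.45, self.model())
        adj = adipose_and_fat_from_water_pr(0.45, self.model(adj=0.967))
        # smaller adjusted water -> more adipose
        assert adj["proportion_adipose"] > raw["proportion_adipose"]

    def test_linear_decreasing_between_limits(self):
        grid = np.linspace(0.25, 0.65, 9)
        vals = [adipose_and_fat_from_water_pr(p, self.model())["proportion_adipose"]
                for p in grid]
        diffs = np.diff(vals)
        assert np.all(diffs < 0)
        assert np.allclose(diffs, diffs[0])  # linearity

    def test_out_of_model_clamped_with_flag(self):
        out = adipose_and_fat_from_water_pr(0.75, self.model())
        assert out["proportion_adipose"] == 0.0
        assert out["clamped"]

    def test_monte_carlo_centered_on_point(self):
        m = WaterFatModel("pace_rathbun", {
            "w_adipose": (0.151, 0.02), "w_lean": (0.732, 0.01),
            "f_adipose": (0.854, 0.02), "water_bias_adjustment": 0.967})
        point = adipose_and_fat_from_water_pr(0.6, m)
        mc = adipose_and_fat_from_water_pr(0.6, m, rng=np.random.default_rng(1),
                                           n_draws=20_000)
        assert mc["proportion_fat"].mean() == pytest.approx(
            point["proportion_fat"], abs=0.01)


def test_config_loads_three_models():
    cfg = load_water_fat_config()
    assert set(cfg) == {"logit", "iverson", "pace_rathbun"}
    assert cfg["iverson"].params["coefficient"] == IVERSON_COEFFICIENT
    # fitted logit: fat decreases as water increases
    assert cfg["logit"].params["alpha1"] < 0
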