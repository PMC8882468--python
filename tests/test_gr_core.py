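import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from grscreen import gr
from grscreen.curves import CurveFit, fit_dose_response, hill_curve

from conftest import tiny_records


def make_fit(plateau, midpoint, hill, scale="GR", dose_min=0.003, dose_max=10.0):
    return CurveFit(scale, plateau, midpoint, hill, "sigmoid", None, 0.0, 96,
                    dose_min, dose_max)


class TestTransforms:
    def test_gr_anchors(self):
        assert gr.gr_value(4.0, 1.0, 4.0) == pytest.approx(1.0)
        assert gr.gr_value(1.0, 1.0, 4.0) == pytest.approx(0.0)
        assert gr.gr_value(2.0, 1.0, 4.0) == pytest.approx(2 ** 0.5 - 1)
        assert gr.gr_value(0.0, 1.0, 4.0) == pytest.approx(-1.0)
        assert gr.gr_value(1e-12, 1.0, 4.0) == pytest.approx(-1.0, abs=1e-5)

    def test_rv_anchors(self):
        assert gr.rv_value(4.0, 1.0, 4.0) == pytest.approx(100.0)
        assert gr.rv_value(1.0, 1.0, 4.0) == pytest.approx(0.0)
        assert gr.rv_value(2.0, 1.0, 4.0) == pytest.approx(100 / 3)
        assert gr.rv_value(0.5, 1.0, 4.0) < 0  # net cell loss

    def test_control_must_grow(self):
        with pytest.raises(ValueError, match="control did not grow"):
            gr.gr_value(1.0, 1.0, 0.9)
        with pytest.raises(ValueError, match="degenerate control"):
            gr.rv_value(1.0, 1.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        t=st.floats(0.1, 10.0), c=st.floats(1.5, 20.0),
        scale=st.floats(1e-3, 1e9),
    )
    def test_gr_scale_invariance(self, t, c, scale):
        """GR depends only on the fold-changes T/T0 and C/T0."""
        base = gr.gr_value(t, 1.0, c)
        rescaled = gr.gr_value(t * scale, scale, c * scale)
        assert rescaled == pytest.approx(base, rel=1e-9)


class TestFitting:
    def test_noiseless_recovery(self):
        doses = np.geomspace(0.003, 10, 8)
        truth = hill_curve(doses, 1.0, -0.5, 0.1, 2.0)
        fit = fit_dose_response(np.tile(doses, 12), np.tile(truth, 12), "GR")
        assert fit.fit_type == "sigmoid"
        assert fit.plateau == pytest.approx(-0.5, rel=0.01)
        assert fit.midpoint == pytest.approx(0.1, rel=0.01)
        assert fit.hill == pytest.approx(2.0, rel=0.01)

    def test_flat_data_gives_flat_fit(self):
        rng = np.random.default_rng(0)
        doses = np.tile(np.geomspace(0.003, 10, 8), 12)
        values = rng.normal(1.0, 0.01, doses.size)
        fit = fit_dose_response(doses, values, "GR")
        assert fit.fit_type == "flat"
        assert fit.flat_level == pytest.approx(1.0, abs=0.01)

    def test_noisy_midpoint_recovery(self):
        rng = np.random.default_rng(1)
        doses = np.tile(np.geomspace(0.003, 10, 8), 12)
        truth = hill_curve(doses, 1.0, 0.0, 0.2, 1.0)
        values = truth * rng.lognormal(0, 0.05, doses.size)
        fit = fit_dose_response(doses, values, "GR")
        assert fit.fit_type == "sigmoid"
        assert fit.midpoint == pytest.approx(0.2, rel=0.15)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct doses"):
            fit_dose_response([0.1, 1, 10], [1, 0.5, 0], "GR")


class TestClosedForms:
    """Closed-form threshold doses must agree with root-finding on the curve."""

    def test_gr50_equals_gec50_at_zero_plateau(self):
        fit = make_fit(0.0, 0.3, 1.7)
        assert gr.gr50(fit) == pytest.approx(0.3)

    def test_gr50_na_when_curve_stays_high(self):
        assert math.isnan(gr.gr50(make_fit(0.8, 0.3, 1.7)))

    def test_cytostatic_anchors(self):
        assert gr.cytostatic_dose(make_fit(-1.0, 0.25, 3.0)) == pytest.approx(0.25)
        assert math.isnan(gr.cytostatic_dose(make_fit(0.2, 0.25, 3.0)))
        assert gr.cytostatic_dose(make_fit(-0.5, 1.0, 2.0)) == pytest.approx(2 ** 0.5)

    def test_gi50_closed_form(self):
        fit = make_fit(-100.0, 0.5, 1.0, scale="RV")
        assert gr.gi50(fit) == pytest.approx(0.5 * ((200 / 150) - 1))
        assert math.isnan(gr.gi50(make_fit(80.0, 0.5, 1.0, scale="RV")))

    @pytest.mark.parametrize("seed", range(4))
    def test_closed_forms_match_bisection(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(250):
            plateau = rng.uniform(-1.0, 0.45)
            fit = make_fit(plateau, float(rng.uniform(0.01, 5.0)),
                           float(rng.uniform(0.3, 4.0)))
            for level, func in ((0.5, gr.gr50), (0.0, gr.cytostatic_dose)):
                expected = math.nan
                if plateau < level:
                    root = brentq(lambda c: fit(c) - level, 1e-12, 1e12,
                                  xtol=1e-15, rtol=1e-13)
                    if func is gr.gr50 and not (
                            fit.dose_min / 10 <= root <= fit.dose_max * 10):
                        root = math.nan
                    expected = root
                got = func(fit)
                if math.isnan(expected):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, rel=1e-6)


class TestAoc:
    def test_constant_curves(self):
        flat1 = CurveFit("GR", None, None, None, "flat", 1.0, 0.0, 96, 0.003, 10.0)
        flatm1 = CurveFit("GR", None, None, None, "flat", -1.0, 0.0, 96, 0.003, 10.0)
        assert gr.gr_aoc(flat1) == pytest.approx(0.0)
        assert gr.gr_aoc(flatm1) == pytest.approx(2.0)

    def test_step_curve_gives_half_area(self):
        # a very steep transition at the geometric center of the log range:
        # GR ~ 1 on the lower half, ~ -1 on the upper half
        fit = make_fit(-1.0, math.sqrt(0.003 * 10.0), 5.0)
        assert gr.gr_aoc(fit, n_grid=2000) == pytest.approx(1.0, abs=0.05)

    def test_bounded_for_bounded_gr(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            fit = make_fit(float(rng.uniform(-1, 1)), float(rng.uniform(0.01, 5)),
                           float(rng.uniform(0.3, 4)))
            assert 0.0 <= gr.gr_aoc(fit) <= 2.0

    def test_single_dose_rejected(self):
        fit = make_fit(0.0, 0.3, 1.0)
        with pytest.raises(ValueError):
            gr.gr_aoc(fit, doses=[1.0])


class TestNormalization:
    def test_noiseless_profile_recovers_truth(self):
        profiles = gr.build_profiles(tiny_records(k=2.0))
        assert len(profiles) == 1
        p = profiles[0]
        assert p.vehicle_fold_pooled == pytest.approx(2.0)
        # GR at each dose must equal the generating Hill truth
        expect = 1.0 - 2.0 * (p.points["dose_uM"] / (p.points["dose_uM"] + 0.1))
        assert np.allclose(p.points["gr"], expect, atol=1e-9)

    def test_fold_change_division(self):
        rec = tiny_records(k=2.0)
        rec.loc[rec["role"] == "treated", "luminescence"] = 3.0e6
        p = gr.build_profiles(rec)[0]
        assert np.allclose(p.points["fold_change"], 3.0)

    def test_missing_vehicle_is_error(self):
        rec = tiny_records()
        rec = rec[rec["role"] != "vehicle"]
        with pytest.raises(ValueError, match="no vehicle wells"):
            gr.build_profiles(rec)

    def test_nongrowing_control_is_error(self):
        rec = tiny_records(k=0.8)
        with pytest.raises(ValueError, match="control did not grow"):
            gr.build_profiles(rec)


class TestDoublingTime:
    def test_exact_doubling(self):
        t = np.arange(0, 24, 4.0)
        assert gr.estimate_doubling_time(t, 2 ** (t / 4.0)) == pytest.approx(4.0)

    def test_constant_signal_is_na(self):
        assert math.isnan(gr.estimate_doubling_time([0, 4, 8], [1, 1, 1]))

    def test_noisy_recovery(self):
        from grscreen.simulate import simulate_growth_curve

        t, y = simulate_growth_curve(6.0, seed=5)
        assert gr.estimate_doubling_time(t, y) == pytest.approx(6.0, abs=0.5)
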