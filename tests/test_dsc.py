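"""DSC processing: baselines, enthalpies, van't Hoff ratio, enthalpy fit."""

import numpy as np
import pytest

import hairpinmelt as hm
from hairpinmelt.dsc import R_KJ, ExcessCurve, auto_onset_offset
from hairpinmelt.simulate import two_state_excess_cp

WIDE = np.arange(250.0, 400.0 + 1e-9, 0.05)


def wide_thermogram(dh_vh=127.1, dh_cal=3.9, tm=316.4, **kw):
    spec = hm.DSCSimSpec(dh_vh=dh_vh, dh_cal=dh_cal, tm=tm,
                         temperatures=WIDE, **kw)
    return hm.generate_dsc_thermogram(spec)[0]


class TestSubtractReference:
    def test_identical_reference_gives_zero(self):
        th = wide_thermogram()
        out = hm.subtract_reference(th, th)
        np.testing.assert_allclose(out.heat_capacity, 0.0, atol=1e-12)

    def test_zero_reference_is_identity(self):
        th = wide_thermogram()
        ref = th.with_heat_capacity(np.zeros(len(th)))
        out = hm.subtract_reference(th, ref)
        np.testing.assert_array_equal(out.heat_capacity, th.heat_capacity)

    def test_shifted_grid_matches_analytic_difference(self):
        # sample and reference are polynomials on different grids; after
        # linear interpolation the difference must match the closed form
        T_s = np.linspace(280, 350, 400)
        T_r = np.linspace(279.5, 350.5, 377)
        sample = hm.DSCThermogram(T_s, 0.002 * T_s**2 - 0.5 * T_s + 3.0)
        ref = hm.DSCThermogram(T_r, 0.1 * T_r - 10.0)
        out = hm.subtract_reference(sample, ref)
        expect = 0.002 * out.temperatures**2 - 0.6 * out.temperatures + 13.0
        np.testing.assert_allclose(out.heat_capacity, expect, atol=1e-6)

    def test_disjoint_ranges_is_error(self):
        a = hm.DSCThermogram(np.linspace(280, 300, 30), np.zeros(30))
        b = hm.DSCThermogram(np.linspace(310, 330, 30), np.zeros(30))
        with pytest.raises(ValueError, match="overlap"):
            hm.subtract_reference(a, b)


class TestExcessHeatCapacity:
    def test_linear_trace_has_zero_excess(self):
        T = np.linspace(280, 350, 200)
        th = hm.DSCThermogram(T, 0.3 * T - 11.0)
        curve = hm.excess_heat_capacity(th, 290.0, 340.0)
        np.testing.assert_allclose(curve.cp_exc, 0.0, atol=1e-9)

    def test_baseline_invariance(self):
        # an added linear instrument baseline must not change the excess
        plain = wide_thermogram()
        tilted = wide_thermogram(baseline_intercept=5.0, baseline_slope=0.02)
        c0 = hm.excess_heat_capacity(plain, WIDE[0], WIDE[-1])
        c1 = hm.excess_heat_capacity(tilted, WIDE[0], WIDE[-1])
        np.testing.assert_allclose(c1.cp_exc, c0.cp_exc, atol=1e-9)

    def test_excess_matches_generation_when_tails_captured(self):
        th = wide_thermogram(baseline_intercept=2.0, baseline_slope=0.01)
        curve = hm.excess_heat_capacity(th, WIDE[0], WIDE[-1])
        truth = two_state_excess_cp(WIDE, 127.1, 3.9, 316.4)
        np.testing.assert_allclose(curve.cp_exc, truth, atol=2e-5)

    def test_peak_near_reference_tm(self):
        curve = hm.excess_heat_capacity(wide_thermogram(), WIDE[0], WIDE[-1])
        tmax = curve.temperatures[np.argmax(curve.cp_exc)]
        assert tmax == pytest.approx(316.4, abs=1.0)

    def test_window_outside_scan_is_error(self):
        with pytest.raises(ValueError, match="outside scan"):
            hm.excess_heat_capacity(wide_thermogram(), 200.0, 340.0)

    def test_zero_outside_window(self):
        curve = hm.excess_heat_capacity(wide_thermogram(), 300.0, 330.0)
        outside = (curve.temperatures < 300) | (curve.temperatures > 330)
        np.testing.assert_array_equal(curve.cp_exc[outside], 0.0)

    def test_auto_window_brackets_transition(self):
        on, off = auto_onset_offset(wide_thermogram(noise_sd=0.002, seed=1))
        assert on < 316.4 < off


class TestEnthalpies:
    def test_zero_curve_integrates_to_zero(self):
        T = np.linspace(280, 350, 100)
        curve = ExcessCurve(T, np.zeros_like(T), 285.0, 345.0, 0.0, 0.0)
        assert hm.calorimetric_enthalpy(curve) == 0.0

    def test_rectangle_area_is_exact(self):
        T = np.linspace(300.0, 310.0, 101)
        curve = ExcessCurve(T, np.full_like(T, 2.5), 300.0, 310.0, 0.0, 0.0)
        assert hm.calorimetric_enthalpy(curve) == pytest.approx(25.0, rel=1e-12)

    def test_reference_parameter_area_within_one_percent(self):
        curve = hm.excess_heat_capacity(wide_thermogram(), WIDE[0], WIDE[-1])
        assert hm.calorimetric_enthalpy(curve) == pytest.approx(3.9, rel=0.01)

    def test_vant_hoff_two_state_self_consistency(self):
        # ΔCp(Tm) = ΔH_cal²/(4·R·Tm²)  =>  ΔH_vH = ΔH_cal (r = 1)
        tm, dh_cal = 316.4, 20.0
        dcp = dh_cal**2 / (4 * R_KJ * tm**2)
        assert hm.vant_hoff_enthalpy(tm, dcp, dh_cal) == \
            pytest.approx(dh_cal, rel=1e-12)

    def test_vant_hoff_zero_dhcal_is_error(self):
        with pytest.raises(ValueError):
            hm.vant_hoff_enthalpy(316.4, 0.1, 0.0)

    def test_eq1_exact_on_closed_form_peak(self):
        # feeding the analytic peak height back through the relation returns
        # ΔH_vH identically
        dh_vh, dh_cal, tm = 127.1, 3.9, 316.4
        peak = dh_cal * dh_vh / (4 * R_KJ * tm**2)
        assert hm.vant_hoff_enthalpy(tm, peak, dh_cal) == \
            pytest.approx(dh_vh, rel=1e-12)

    @pytest.mark.parametrize("dh_vh", [80.0, 127.1, 250.0])
    @pytest.mark.parametrize("dh_cal", [3.9, 20.0, 80.0])
    @pytest.mark.parametrize("tm", [300.0, 316.4, 330.0])
    def test_round_trip_recovery_grid(self, dh_vh, dh_cal, tm):
        spec = hm.DSCSimSpec(dh_vh=dh_vh, dh_cal=dh_cal, tm=tm,
                             temperatures=np.arange(220.0, 420.0, 0.05))
        th, _ = hm.generate_dsc_thermogram(spec)
        res = hm.DSCAnalysis(th, onset=220.0, offset=419.0).fit()
        assert res.dh_cal == pytest.approx(dh_cal, rel=0.02)
        assert res.dh_vh == pytest.approx(dh_vh, rel=0.02)


class TestVantHoffRatio:
    def test_equal_enthalpies_two_state(self):
        r, verdict = hm.vant_hoff_ratio(20.0, 20.0)
        assert r == 1.0 and verdict == "two-state"

    def test_reference_enthalpies_give_noncooperative_ratio(self):
        r, verdict = hm.vant_hoff_ratio(127.1, 3.9)
        assert r == pytest.approx(32.6, abs=0.1)
        assert verdict == "non-cooperative"

    def test_half_ratio_round_trip(self):
        # generator configured at r = 0.5 comes back through the full chain
        spec = hm.DSCSimSpec(dh_vh=60.0, dh_cal=120.0, tm=316.0,
                             temperatures=np.arange(200.0, 450.0, 0.05))
        th, _ = hm.generate_dsc_thermogram(spec)
        res = hm.DSCAnalysis(th, onset=200.0, offset=449.0).fit()
        assert res.r_vh == pytest.approx(0.5, rel=0.02)


class TestExcessEnthalpyFit:
    def test_exact_logistic_recovery(self):
        # build an excess curve whose cumulative integral IS the logistic;
        # the window spans ±15 widths so the tails are numerically complete
        dh, t_half, w = 3.9, 316.4, 6.0
        T = np.linspace(t_half - 15 * w, t_half + 15 * w, 2000)
        e = np.exp((T - t_half) / w)
        cp = dh * e / (w * (1 + e) ** 2)   # derivative of the logistic
        curve = ExcessCurve(T, cp, T[0], T[-1], 0.0, 0.0)
        fit = hm.excess_enthalpy_fit(curve)
        assert fit.converged
        assert fit.dh_cal_fit == pytest.approx(dh, rel=1e-4)
        assert fit.t_half == pytest.approx(t_half, abs=1e-3)
        assert fit.width == pytest.approx(w, rel=1e-3)

    def test_reference_parameters_t_half_near_peak(self):
        res = hm.DSCAnalysis(wide_thermogram(), onset=WIDE[0], offset=WIDE[-1]).fit()
        assert res.enthalpy_fit.converged
        assert res.enthalpy_fit.t_half == pytest.approx(res.tm, abs=1.0)

    def test_plateau_matches_total_integral(self):
        curve = hm.excess_heat_capacity(wide_thermogram(), WIDE[0], WIDE[-1])
        fit = hm.excess_enthalpy_fit(curve)
        assert fit.dh_cal_fit == pytest.approx(hm.calorimetric_enthalpy(curve),
                                               rel=0.01)


class TestFullPipelineInvariants:
    @pytest.mark.parametrize("r_target", [1.0, 5.0, 32.0])
    def test_noiseless_ratio_recovery(self, r_target):
        dh_vh = 127.1
        spec = hm.DSCSimSpec(dh_vh=dh_vh, dh_cal=dh_vh / r_target, tm=316.4,
                             temperatures=np.arange(220.0, 420.0, 0.05))
        th, _ = hm.generate_dsc_thermogram(spec)
        res = hm.DSCAnalysis(th, onset=220.0, offset=419.0).fit()
        assert res.r_vh == pytest.approx(r_target, rel=0.05)

    def test_noisy_ratio_recovery_median(self):
        # 2% of peak height noise; median recovered ratio within 15%
        dh_vh, dh_cal, tm = 127.1, 3.9, 316.4
        peak = dh_cal * dh_vh / (4 * R_KJ * tm**2)
        rs = []
        for seed in range(20):
            spec = hm.DSCSimSpec(dh_vh=dh_vh, dh_cal=dh_cal, tm=tm,
                                 noise_sd=0.02 * peak, seed=seed,
                                 temperatures=np.arange(250.0, 400.0, 0.1))
            th, _ = hm.generate_dsc_thermogram(spec)
            res = hm.DSCAnalysis(th, onset=250.0, offset=399.9).fit()
            rs.append(res.r_vh)
        assert np.median(rs) == pytest.approx(dh_vh / dh_cal, rel=0.15)

    def test_baseline_invariance_of_all_outputs(self):
        plain = hm.DSCAnalysis(wide_thermogram(), onset=WIDE[0],
                               offset=WIDE[-1]).fit()
        tilted = hm.DSCAnalysis(
            wide_thermogram(baseline_intercept=-3.0, baseline_slope=0.05),
            onset=WIDE[0], offset=WIDE[-1]).fit()
        assert tilted.dh_cal == pytest.approx(plain.dh_cal, rel=1e-6)
        assert tilted.dh_vh == pytest.approx(plain.dh_vh, rel=1e-6)
        assert tilted.r_vh == pytest.approx(plain.r_vh, rel=1e-6)
        assert tilted.tm == plain.tm
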