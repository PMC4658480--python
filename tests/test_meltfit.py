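"""Sigmoid evaluation, fitting, oracle dominance and curve selection."""

import numpy as np
import pytest

import hairpinmelt as hm
from hairpinmelt.meltfit import MeltCurveModel

P5 = hm.ProtonID(5, "HE1", "W")


def make_series(T, params, noise_sd=0.0, seed=0, proton=P5):
    clean = hm.boltzmann_sigmoid(T, *params)
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.normal(0, noise_sd, T.shape) if noise_sd else 0.0)
    return hm.MeltSeries(proton, T, noisy)


def grid_oracle_ssr(series, nx=81, ndx=41):
    """Independent dense (x0, dx) grid search, linear solve at every node.

    Returns the smallest residual sum of squares over the grid; any good
    5-parameter fit must do at least as well.
    """
    T, d = series.temperatures, series.shifts
    best = np.inf
    for x0 in np.linspace(T[0], T[-1], nx):
        for dx in np.linspace(0.5, 20.0, ndx):
            s = 1.0 / (1.0 + np.exp((T - x0) / dx))
            X = np.column_stack([s, 1.0 - s, T - x0])
            coef, *_ = np.linalg.lstsq(X, d, rcond=None)
            best = min(best, float(np.sum((d - X @ coef) ** 2)))
    return best


class TestEvalMeltModel:
    def test_midpoint_is_baseline_plus_mean_amplitude(self):
        val = hm.eval_melt_model(316.0, 8.0, 8.4, 0.002, 316.0, 5.0)
        assert val == pytest.approx(0.5 * (8.0 + 8.4), rel=1e-12)

    def test_degenerate_sigmoid_is_constant(self, grid_14):
        vals = hm.eval_melt_model(grid_14, 8.0, 8.0, 0.0, 316.0, 5.0)
        np.testing.assert_allclose(vals, 8.0, rtol=1e-12)

    def test_closed_form_value(self):
        # A1 + (A2-A1)·(1 − 1/(1+e^((T−x0)/dx))) at T = x0 + 2·dx
        val = hm.eval_melt_model(326.0, 8.0, 8.4, 0.0, 316.0, 5.0)
        assert val == pytest.approx(8.0 + 0.4 / (1 + np.exp(-2.0)), rel=1e-12)

    def test_plateaus(self):
        assert hm.eval_melt_model(100.0, 1.0, 2.0, 0.0, 316.0, 5.0) == \
            pytest.approx(1.0, abs=1e-12)
        assert hm.eval_melt_model(600.0, 1.0, 2.0, 0.0, 316.0, 5.0) == \
            pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_width_is_error(self):
        with pytest.raises(ValueError, match="dx"):
            hm.eval_melt_model(300.0, 1.0, 2.0, 0.0, 316.0, 0.0)


class TestFitMeltCurve:
    @pytest.mark.parametrize("params", [
        (8.0, 8.4, 0.0, 316.0, 5.0),
        (4.5, 4.1, 0.002, 310.0, 3.0),
        (7.2, 7.5, -0.001, 320.0, 8.0),
    ])
    def test_noiseless_exact_recovery(self, grid_14, params):
        fit = hm.fit_melt_curve(make_series(grid_14, params))
        assert fit.converged
        for got, want in zip(fit.params, params):
            tol = 1e-6 * max(abs(want), 1e-3)
            assert abs(got - want) < tol

    def test_short_series_is_error(self):
        with pytest.raises(ValueError, match=">= 6"):
            hm.MeltSeries(P5, np.array([280.0, 290, 300, 310, 320]),
                          np.zeros(5))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_grid_search_oracle_dominance(self, grid_14, seed):
        # the returned least-squares objective beats a dense independent grid
        series = make_series(grid_14, (4.4, 4.7, 0.001, 317.0, 5.0),
                             noise_sd=0.01, seed=seed)
        fit = hm.fit_melt_curve(series)
        ssr_fit = float(np.sum((series.shifts - fit.predict(grid_14)) ** 2))
        assert ssr_fit <= grid_oracle_ssr(series) * (1 + 1e-9)

    def test_default_dataset_tms_in_reported_range(self, default_fits):
        # all fitted midpoints fall within the observed Tm range +/- 2 K
        tms = [f.tm for f in default_fits if f.converged]
        assert len(tms) >= 28
        assert min(tms) > 315.6 - 2.0
        assert max(tms) < 321.5 + 2.0

    def test_shift_offset_equivariance(self, grid_14):
        params = (4.4, 4.7, 0.001, 317.0, 5.0)
        s = make_series(grid_14, params)
        shifted = hm.MeltSeries(P5, grid_14, s.shifts + 1.7)
        f0, f1 = hm.fit_melt_curve(s), hm.fit_melt_curve(shifted)
        assert f1.A1 - f0.A1 == pytest.approx(1.7, abs=1e-6)
        assert f1.A2 - f0.A2 == pytest.approx(1.7, abs=1e-6)
        for i in (2, 3, 4):  # B, x0, dx untouched
            assert f1.params[i] == pytest.approx(f0.params[i], abs=1e-8)

    def test_transition_direction_indifference(self, grid_14):
        up = make_series(grid_14, (4.4, 4.8, 0.0, 317.0, 5.0))
        down = make_series(grid_14, (4.8, 4.4, 0.0, 317.0, 5.0))
        f_up, f_down = hm.fit_melt_curve(up), hm.fit_melt_curve(down)
        assert f_up.x0 == pytest.approx(f_down.x0, abs=1e-6)
        assert f_up.dx == pytest.approx(f_down.dx, abs=1e-6)

    def test_median_tm_error_monotone_in_noise(self, grid_14):
        params = (4.4, 4.7, 0.001, 317.0, 5.0)
        medians = []
        for noise in (0.0, 0.005, 0.02, 0.05):
            errs = []
            for seed in range(50):
                fit = hm.fit_melt_curve(make_series(grid_14, params,
                                                    noise_sd=noise, seed=seed))
                errs.append(abs(fit.tm - 317.0))
            medians.append(np.median(errs))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:]))

    def test_weighted_fit_matches_unweighted_for_equal_weights(self, grid_14):
        s = make_series(grid_14, (4.4, 4.7, 0.001, 317.0, 5.0),
                        noise_sd=0.01, seed=3)
        f0 = hm.fit_melt_curve(s)
        f1 = hm.fit_melt_curve(s, weights=np.full(len(s), 0.01))
        np.testing.assert_allclose(f1.params, f0.params, rtol=1e-5, atol=1e-8)


class TestFilterFits:
    def test_flat_noise_rejected_for_amplitude(self, grid_14):
        rng = np.random.default_rng(0)
        s = hm.MeltSeries(P5, grid_14, 4.4 + rng.normal(0, 0.01, grid_14.shape))
        _, rejected = hm.filter_fits([hm.fit_melt_curve(s)])
        assert len(rejected) == 1
        assert rejected[0].reason == "amplitude-below-threshold"

    def test_known_composition_fixture(self, grid_14):
        rng = np.random.default_rng(1)
        series = []
        for i in range(30):  # clear sigmoids
            series.append(make_series(
                grid_14, (4.4, 4.7, 0.0, 310.0 + 0.5 * i, 4.0),
                noise_sd=0.005, seed=i, proton=hm.ProtonID(i + 1, "HA")))
        for i in range(5):   # flat noise
            series.append(hm.MeltSeries(
                hm.ProtonID(40 + i, "HN"), grid_14,
                8.3 + rng.normal(0, 0.01, grid_14.shape)))
        fits = [hm.fit_melt_curve(s) for s in series]
        accepted, rejected = hm.filter_fits(fits)
        assert len(accepted) == 30
        assert len(rejected) == 5
        assert {r.fit.proton.residue_number for r in rejected} == set(range(40, 45))

    def test_noiseless_set_has_zero_rejections(self, grid_14):
        series = [make_series(grid_14, (4.4, 4.7, 0.001, 310.0 + i, 4.0),
                              proton=hm.ProtonID(i + 1, "HA"))
                  for i in range(10)]
        accepted, rejected = hm.filter_fits([hm.fit_melt_curve(s) for s in series])
        assert rejected == []
        assert len(accepted) == 10

    def test_empty_input_gives_two_empty_sets(self):
        assert hm.filter_fits([]) == ([], [])

    def test_partition_is_exhaustive_and_disjoint(self, default_fits):
        accepted, rejected = hm.filter_fits(default_fits)
        assert len(accepted) + len(rejected) == len(default_fits)
        ids = [f.proton for f in accepted] + [r.fit.proton for r in rejected]
        assert len(set(ids)) == len(ids)


def test_start_params_linear_solver_is_exact(grid_14):
    # with (x0, dx) fixed at truth the linear solve recovers A1, A2, B exactly
    params = (4.4, 4.7, 0.0015, 317.0, 5.0)
    s = make_series(grid_14, params)
    solved, ssr = MeltCurveModel._solve_linear(grid_14, s.shifts, 317.0, 5.0)
    np.testing.assert_allclose(solved[:3], params[:3], rtol=1e-9)
    assert ssr < 1e-18
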