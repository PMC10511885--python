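"""Objective function, bounded fitting and the initialization grid search."""

import numpy as np
import pytest

import bivalentfit as bf
from bivalentfit.estimation import default_local_init


class TestParameterPacking:
    def test_round_trip_and_names(self, small_truth):
        x = small_truth.to_array()
        assert x.shape == (10,)  # 4 + 2*3
        back = bf.ParameterVector.from_array(x, 3)
        assert np.array_equal(back.to_array(), x)
        assert back.names()[:4] == ["ka1", "kd1", "ka2", "kd2"]
        assert back.names()[4:6] == ["rmax_1", "tstar_1"]

    def test_regenerative_packing_drops_tstar(self):
        p = bf.ParameterVector(bf.RateConstants(1, 1, 1, 1),
                               [bf.CycleParams(10.0)] * 5,
                               regenerative=True)
        assert p.n_params == 9
        assert "tstar_1" not in p.names()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            bf.ParameterVector.from_array(np.zeros(7), 2)


class TestSse:
    def test_zero_at_generating_parameters(self, small_truth, small_design):
        """The objective vanishes at the truth on noiseless data, with
        the reference integrator generating the observations."""
        clean = bf.simulate_titration(small_truth.globals_,
                                      small_truth.locals_, small_design,
                                      method="scipy")
        assert bf.sse(small_truth, clean) <= 1e-8

    def test_constant_offset_arithmetic(self, small_truth, small_series):
        shifted = bf.TitrationSeries(cycles=[
            bf.CyclePhases(c.analyte_conc, c.time, c.response + 2.0, c.phase)
            for c in small_series.cycles])
        n = small_series.n_points
        assert bf.sse(small_truth, shifted) == pytest.approx(4.0 * n,
                                                             rel=1e-9)

    def test_residual_homogeneity(self, small_truth, small_series):
        def with_offset(d):
            return bf.TitrationSeries(cycles=[
                bf.CyclePhases(c.analyte_conc, c.time, c.response + d,
                               c.phase)
                for c in small_series.cycles])
        s1 = bf.sse(small_truth, with_offset(1.5))
        s2 = bf.sse(small_truth, with_offset(3.0))
        assert s2 == pytest.approx(4.0 * s1, rel=1e-9)

    def test_cycle_count_mismatch(self, small_truth, small_series):
        one = bf.TitrationSeries(cycles=small_series.cycles[:1])
        with pytest.raises(ValueError):
            bf.sse(small_truth, one)


class TestFitGlobal:
    def test_fixed_point_at_truth(self, truth, standard_noiseless):
        res = bf.fit_global(standard_noiseless, truth, bf.FitConfig(sigma=6.0))
        assert res.converged
        assert res.sse <= 1e-6
        assert np.allclose(res.estimate.to_array(), truth.to_array(),
                           rtol=1e-4)

    def test_recovery_from_doubled_start(self, truth, extended_noiseless):
        """All four rate constants recovered to <=1% from a start with
        every global parameter doubled, on noiseless data."""
        k = truth.globals_
        start = bf.ParameterVector(
            bf.RateConstants(2 * k.ka1, 2 * k.kd1, 2 * k.ka2, 2 * k.kd2),
            truth.locals_)
        res = bf.fit_global(extended_noiseless, start, bf.FitConfig(sigma=6.0))
        got = res.rate_constants.as_array()
        assert np.all(np.abs(got / k.as_array() - 1.0) <= 0.01)

    def test_nonconvergence_is_flagged_not_raised(self, truth,
                                                  standard_noiseless):
        cfg = bf.FitConfig(sigma=6.0, max_nfev=2)
        start = bf.ParameterVector(bf.RateConstants(1e2, 1e-2, 1e-3, 1e-3),
                                   truth.locals_)
        res = bf.fit_global(standard_noiseless, start, cfg)
        assert res.converged is False

    def test_clamped_coordinate_stays_clamped(self, truth,
                                              standard_noiseless):
        res = bf.fit_global(standard_noiseless, truth,
                            bf.FitConfig(sigma=6.0), fixed={3: 2e-5})
        assert res.estimate.globals_.kd2 == 2e-5
        assert np.isnan(res.standard_errors[3])

    def test_start_outside_bounds_rejected(self, truth, small_series):
        bad = truth.to_array().copy()
        with pytest.raises(ValueError):
            bf.fit_global(small_series, truth, fixed={0: -1.0})


class TestGridSearch:
    def test_single_point_grid_reduces_to_fit_global(self, small_series):
        cfg = bf.FitConfig(
            sigma=6.0,
            grid={"ka1": [2e3], "kd1": [4e-3], "ka2": [5e-5], "kd2": [1e-5]})
        gs = bf.grid_search(small_series, cfg)
        assert len(gs.fits) == 1
        start = bf.ParameterVector(bf.RateConstants(2e3, 4e-3, 5e-5, 1e-5),
                                   default_local_init(small_series, cfg))
        solo = bf.fit_global(small_series, start, cfg)
        assert gs.best.sse == pytest.approx(solo.sse, rel=1e-9)

    def test_best_dominates_all_starts(self, small_series):
        cfg = bf.FitConfig(
            sigma=6.0,
            grid={"ka1": [1e3, 1e4], "kd1": [1e-3], "ka2": [1e-4],
                  "kd2": [1e-4]})
        gs = bf.grid_search(small_series, cfg)
        assert len(gs.fits) == 2
        assert all(gs.best.sse <= f.sse + 1e-12 for f in gs.fits)
        assert gs.labels[gs.best_index] == "global"

    def test_deterministic_across_runs(self, small_series, fast_cfg):
        cfg = bf.FitConfig(
            sigma=6.0,
            grid={"ka1": [1e3], "kd1": [1e-3, 1e-2], "ka2": [1e-4],
                  "kd2": [1e-4]})
        a = bf.grid_search(small_series, cfg)
        b = bf.grid_search(small_series, cfg)
        assert a.best.sse == b.best.sse
        assert np.array_equal(a.best.estimate.to_array(),
                              b.best.estimate.to_array())

    def test_empty_axis_rejected(self, small_series):
        with pytest.raises(ValueError):
            cfg = bf.FitConfig(sigma=6.0)
            cfg.grid["kd2"] = []
            bf.grid_search(small_series, cfg)


class TestEstimateSigma:
    def test_arithmetic(self, small_truth, small_series):
        n = small_series.n_points
        p = small_truth.n_params
        fake = bf.FitResult(estimate=small_truth, sse=4.0 * (n - p),
                            converged=True, n_iter=1, start=small_truth,
                            standard_errors=np.zeros(p))
        assert bf.estimate_sigma(fake, small_series) == pytest.approx(2.0)

    def test_noiseless_is_near_zero(self, truth, standard_noiseless):
        res = bf.fit_global(standard_noiseless, truth, bf.FitConfig(sigma=6.0))
        assert bf.estimate_sigma(res, standard_noiseless) <= 1e-4

    def test_recovers_generating_noise_sd(self, truth):
        """Monte-Carlo check: residual SD of a converged fit on sigma=6
        noise, N >= 5000, lands within 10% of 6 RU."""
        sc = bf.extended_scenario(seed=11)
        series = bf.generate_noisy_titration(sc, 0)
        res = bf.fit_global(series, truth, bf.FitConfig(sigma=6.0))
        assert bf.estimate_sigma(res, series) == pytest.approx(6.0, rel=0.1)

    def test_underdetermined_rejected(self, small_truth):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        phase = np.array(["association"] * 2 + ["dissociation"] * 2,
                         dtype=object)
        tiny = bf.TitrationSeries(cycles=[
            bf.CyclePhases(1e-6, t, np.zeros(4), phase)])
        fake = bf.FitResult(estimate=small_truth, sse=1.0, converged=True,
                            n_iter=1, start=small_truth,
                            standard_errors=np.zeros(10))
        with pytest.raises(ValueError):
            bf.estimate_sigma(fake, tiny)
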