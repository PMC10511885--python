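"""Model mathematics: right-hand sides, closed forms, simulation limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import bivalentfit as bf
from bivalentfit.kinetics import dissociation_closed_form

rates = st.floats(min_value=0.0, max_value=1e-2, allow_nan=False)
levels = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestRightHandSides:
    def test_association_null_state(self):
        k = bf.RateConstants(2e3, 4e-3, 5e-5, 1e-5)
        assert bf.association_rhs((0, 0, 0), k, 1e-6) == (0.0, 0.0, 0.0)

    def test_association_first_step_flux(self):
        # bare surface, only ka1 active: dL/dt = -2*ka1*Am*L
        k = bf.RateConstants(2e3, 0.0, 0.0, 0.0)
        dL, dAL1, dAL2 = bf.association_rhs((600, 0, 0), k, 1e-6)
        assert dL == pytest.approx(-2.4, abs=1e-12)
        assert dAL1 == pytest.approx(2.4, abs=1e-12)
        assert dAL2 == 0.0

    def test_dissociation_flux(self):
        k = bf.RateConstants(0.0, 4e-3, 0.0, 1e-5)
        dL, dAL1, dAL2 = bf.dissociation_rhs((0, 100, 50), k)
        assert dAL2 == pytest.approx(-1e-3, rel=1e-12)
        assert dAL1 == pytest.approx(-0.399, rel=1e-12)
        assert dL == pytest.approx(0.401, rel=1e-12)

    @given(L=levels, al1=levels, al2=levels, ka1=rates, kd1=rates,
           ka2=rates, kd2=rates, am=st.floats(min_value=0, max_value=1e-5))
    @settings(max_examples=100, deadline=None)
    def test_ligand_site_conservation_identity(self, L, al1, al2, ka1, kd1,
                                               ka2, kd2, am):
        """dL + dAL1 + 2*dAL2 = 0 for both phase models."""
        k = bf.RateConstants(ka1, kd1, ka2, kd2)
        for d in (bf.association_rhs((L, al1, al2), k, am),
                  bf.dissociation_rhs((L, al1, al2), k)):
            assert d[0] + d[1] + 2 * d[2] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("state", [(np.nan, 0, 0), (0, np.inf, 0)])
    def test_non_finite_state_rejected(self, state):
        k = bf.RateConstants(1e3, 1e-3, 1e-4, 1e-4)
        with pytest.raises(ValueError):
            bf.association_rhs(state, k, 1e-6)
        with pytest.raises(ValueError):
            bf.dissociation_rhs(state, k)


class TestDissociationClosedForm:
    K = bf.RateConstants(0.0, 4e-3, 0.0, 1e-5)

    def test_identity_at_time_zero(self):
        out = dissociation_closed_form((450, 100, 50), self.K, 0.0)
        assert np.allclose(out[0], [450, 100, 50], rtol=0, atol=0)

    def test_pure_exponential_limit(self):
        k = bf.RateConstants(0.0, 4e-3, 0.0, 0.0)
        out = dissociation_closed_form((0, 100, 0), k, [250.0])
        assert out[0, 1] == pytest.approx(100 * np.exp(-4e-3 * 250), rel=1e-12)

    def test_two_step_decay_values(self):
        # frozen from scalar evaluation of the analytic solution
        out = dissociation_closed_form((0, 100, 50), self.K, [600.0])
        assert out[0, 2] == pytest.approx(49.4036, rel=1e-4)
        assert out[0, 1] == pytest.approx(9.2973, rel=1e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dissociation_closed_form((0, 1, 1), self.K, -1.0)

    @pytest.mark.parametrize("kd1,kd2", [
        (4e-3, 1e-5), (1e-1, 1e-6), (1e-6, 1e-1), (2e-4, 1e-4 + 1e-16),
    ])
    def test_matches_numeric_integration(self, kd1, kd2):
        """Closed form vs independent ODE integration over 1800 s for
        rates spanning 1e-6..1e-1 1/s, including the kd1 ~ 2*kd2
        degenerate branch."""
        k = bf.RateConstants(0.0, kd1, 0.0, kd2)
        t = np.linspace(0, 1800, 61)
        sol = solve_ivp(lambda _, y: bf.dissociation_rhs(y, k),
                        (0, 1800), [0.0, 100.0, 50.0], t_eval=t,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        closed = dissociation_closed_form((0, 100, 50), k, t)
        assert np.allclose(sol.y[1], closed[:, 1], rtol=1e-6, atol=1e-8)
        assert np.allclose(sol.y[2], closed[:, 2], rtol=1e-6, atol=1e-8)


class TestSimulateCycle:
    CD = bf.CycleDesign(analyte_conc=1e-6, t_assoc=300.0, t_dissoc=600.0)

    def test_no_analyte_is_flat(self):
        cd = bf.CycleDesign(analyte_conc=0.0, t_assoc=300.0, t_dissoc=600.0)
        k = bf.RateConstants(2e3, 4e-3, 5e-5, 1e-5)
        _, _, states = bf.simulate_cycle(k, bf.CycleParams(600.0, 0.0), cd)
        assert np.allclose(bf.predict_response(states), 0.0, atol=1e-12)

    def test_one_to_one_langmuir_limit(self):
        """With ka2 = kd2 = 0 the association phase is the 1:1 Langmuir
        model with the bivalent factor of two on the on-rate."""
        ka1, kd1, am, rmax = 2e3, 4e-3, 1e-6, 600.0
        k = bf.RateConstants(ka1, kd1, 0.0, 0.0)
        t, phase, states = bf.simulate_cycle(k, bf.CycleParams(rmax, 0.0),
                                             self.CD)
        mask = phase == "association"
        kobs = 2 * ka1 * am + kd1
        amp = 2 * ka1 * am * rmax / kobs
        expected = amp * (1 - np.exp(-kobs * t[mask]))
        got = bf.predict_response(states[mask])
        assert np.allclose(got, expected, rtol=1e-6, atol=1e-8)

    def test_langmuir_plateau_300_RU(self):
        k = bf.RateConstants(2e3, 4e-3, 0.0, 0.0)
        cd = bf.CycleDesign(analyte_conc=1e-6, t_assoc=20000.0,
                            t_dissoc=100.0, dt=100.0)
        _, phase, states = bf.simulate_cycle(k, bf.CycleParams(600.0, 0.0), cd)
        plateau = bf.predict_response(states[phase == "association"])[-1]
        assert plateau == pytest.approx(300.0, rel=1e-4)

    def test_fast_route_matches_scipy_route(self, truth_rates):
        cp = bf.CycleParams(600.0, 150.0)
        _, _, fast = bf.simulate_cycle(truth_rates, cp, self.CD)
        _, _, ref = bf.simulate_cycle(truth_rates, cp, self.CD,
                                      method="scipy")
        assert np.allclose(bf.predict_response(fast),
                           bf.predict_response(ref), rtol=1e-6, atol=1e-6)

    def test_conservation_along_trajectory(self, truth_rates):
        """L + AL1 + 2*AL2 drifts by <= 1e-8 (relative) along the full
        3-state reference integration at default tolerances."""
        cp = bf.CycleParams(600.0, 150.0)
        _, _, states = bf.simulate_cycle(truth_rates, cp, self.CD,
                                         method="scipy")
        total = states[:, 0] + states[:, 1] + 2 * states[:, 2]
        assert np.max(np.abs(total - 600.0)) / 600.0 <= 1e-8

    def test_phase_monotonicity(self, truth_rates):
        t, phase, states = bf.simulate_cycle(
            truth_rates, bf.CycleParams(600.0, 0.0), self.CD)
        resp = bf.predict_response(states)
        assoc = resp[phase == "association"]
        diss = resp[phase == "dissociation"]
        assert np.all(np.diff(assoc) >= -1e-9)
        assert np.all(np.diff(diss) <= 1e-9)


class TestPredictResponse:
    def test_counts_each_bound_analyte_once(self):
        assert bf.predict_response(np.array([[600.0, 0.0, 0.0]]))[0] == 0.0
        assert bf.predict_response(np.array([[0.0, 100.0, 50.0]]))[0] == 150.0

    def test_free_ligand_excluded(self):
        out = bf.predict_response(np.array([[123.0, 10.0, 5.0]]))
        assert out[0] == 15.0


class TestSimulateTitration:
    def test_single_cycle_composition(self, truth_rates):
        cd = bf.CycleDesign(analyte_conc=5e-7, t_assoc=100.0,
                            t_dissoc=200.0, dt=10.0)
        td = bf.TitrationDesign([cd])
        cp = bf.CycleParams(600.0, 30.0)
        series = bf.simulate_titration(truth_rates, [cp], td)
        _, _, states = bf.simulate_cycle(truth_rates, cp, cd)
        assert np.allclose(series.cycles[0].response,
                           bf.predict_response(states), rtol=0, atol=0)

    def test_zero_rates_flat(self, small_design):
        k = bf.RateConstants(0, 0, 0, 0)
        cps = [bf.CycleParams(600.0, 0.0)] * 3
        series = bf.simulate_titration(k, cps, small_design)
        assert np.allclose(series.responses(), 0.0, atol=0)

    def test_cycle_params_length_mismatch(self, truth_rates, small_design):
        with pytest.raises(ValueError):
            bf.simulate_titration(truth_rates, [bf.CycleParams(600.0)],
                                  small_design)

    def test_regenerative_ignores_tstar(self, truth_rates):
        cd = bf.CycleDesign(analyte_conc=5e-7, t_assoc=100.0,
                            t_dissoc=100.0, dt=10.0)
        td_r = bf.TitrationDesign([cd], regenerative=True)
        with_t = bf.simulate_titration(truth_rates,
                                       [bf.CycleParams(600.0, 150.0)], td_r)
        without = bf.simulate_titration(truth_rates,
                                        [bf.CycleParams(600.0, 0.0)], td_r)
        assert np.allclose(with_t.responses(), without.responses())

    def test_dose_monotone_plateaus(self, standard_noiseless):
        """End-of-association response is non-decreasing in analyte
        concentration for the simulation-study parameters."""
        ends = [c.response[c.assoc_mask][-1]
                for c in standard_noiseless.cycles]
        assert np.all(np.diff(ends) >= 0)


class TestDesignValidation:
    def test_non_regenerative_requires_increasing_conc(self):
        cds = [bf.CycleDesign(analyte_conc=c, t_assoc=10, t_dissoc=10)
               for c in (1e-6, 5e-7)]
        with pytest.raises(ValueError):
            bf.TitrationDesign(cds)
        # the same ladder is fine when regenerative
        bf.TitrationDesign(cds, regenerative=True)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            bf.RateConstants(-1.0, 0, 0, 0)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            bf.TitrationDesign([])
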