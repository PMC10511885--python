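import numpy as np
import pytest

import bivalentfit as bf


@pytest.fixture(scope="session")
def truth():
    """Simulation-study generating parameter vector."""
    return bf.simulation_truth()


@pytest.fixture(scope="session")
def truth_rates(truth):
    return truth.globals_


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down titration design for fast fitting tests: 3 doubling
    concentrations, coarse 10 s sampling, short phases."""
    cycles = [bf.CycleDesign(analyte_conc=c, t_assoc=100.0, t_dissoc=200.0,
                             dt=10.0)
              for c in (2.5e-7, 5e-7, 1e-6)]
    return bf.TitrationDesign(cycles)


@pytest.fixture(scope="session")
def small_truth():
    locs = [bf.CycleParams(rmax=600.0, tstar=t) for t in (50.0, 40.0, 30.0)]
    return bf.ParameterVector(bf.RateConstants(2e3, 4e-3, 5e-5, 1e-5), locs)


@pytest.fixture(scope="session")
def small_series(small_truth, small_design):
    """Noiseless scaled-down titration."""
    return bf.simulate_titration(small_truth.globals_, small_truth.locals_,
                                 small_design)


@pytest.fixture(scope="session")
def standard_noiseless(truth):
    sc = bf.standard_scenario()
    return bf.simulate_titration(truth.globals_, truth.locals_, sc.design)


@pytest.fixture(scope="session")
def extended_noiseless(truth):
    sc = bf.extended_scenario()
    return bf.simulate_titration(truth.globals_, truth.locals_, sc.design)


@pytest.fixture()
def fast_cfg():
    """Config with the scaled-down exploration grid used in tests."""
    return bf.FitConfig(
        sigma=6.0,
        grid={"ka1": [1e2, 1e4], "kd1": [1e-4, 1e-2],
              "ka2": [1e-5, 1e-3], "kd2": [1e-5, 1e-3]})
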