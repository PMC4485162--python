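import logging

import pytest

from xyleth.parameters import ParameterSet, derive_physiology
from xyleth.simulate import SolverConfig, default_study_scenario, simulate

logging.getLogger("xyleth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def central_params() -> ParameterSet:
    return ParameterSet.central()


@pytest.fixture(scope="session")
def central_phys(central_params):
    return derive_physiology(central_params)


@pytest.fixture(scope="session")
def scenario_noeth():
    return default_study_scenario(with_ethanol=False, exposure_ppm=50.0)


@pytest.fixture(scope="session")
def scenario_eth():
    return default_study_scenario(with_ethanol=True, exposure_ppm=50.0)


@pytest.fixture(scope="session")
def fast_solver():
    # coarse dense grid; observation times are still evaluated exactly
    return SolverConfig(method="rk4", dt=0.005, dense_dt=0.25)


@pytest.fixture(scope="session")
def central_run_noeth(central_params, scenario_noeth):
    return simulate(central_params, scenario_noeth)


@pytest.fixture(scope="session")
def central_run_eth(central_params, scenario_eth):
    return simulate(central_params, scenario_eth)
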