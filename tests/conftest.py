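import numpy as np
import pytest

import agingnet as ag


@pytest.fixture(scope="session")
def ref_params() -> ag.RateParameters:
    """Reference calibration of the health-network model."""
    return ag.preset_rate_parameters("mitnitski2017")


@pytest.fixture(scope="session")
def ref_solution(ref_params) -> ag.MeanFieldSolution:
    return ag.solve_meanfield(ref_params)


@pytest.fixture(scope="session")
def ref_hazard_curve(ref_solution) -> ag.HazardCurve:
    return ag.meanfield_hazard_curve(ref_solution)


@pytest.fixture(scope="session")
def pair_network() -> ag.HealthNetwork:
    """Two mutually adjacent nodes, both of them mortality nodes."""
    return ag.HealthNetwork.from_edges(2, [(0, 1)], mortality_nodes=(0, 1))


@pytest.fixture(scope="session")
def small_network() -> ag.HealthNetwork:
    """Complete graph on 3 nodes; mortality nodes 0 and 1."""
    return ag.HealthNetwork.from_edges(3, [(0, 1), (0, 2), (1, 2)], mortality_nodes=(0, 1))


@pytest.fixture(scope="session")
def generated_network() -> ag.HealthNetwork:
    """Mid-sized scale-free disassortative network shared across tests."""
    return ag.generate_network(2000, 2, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
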