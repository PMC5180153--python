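"""Shared fixtures: small ensembles and one fully simulated community."""

import numpy as np
import pytest

import phagenet as pn


@pytest.fixture(scope="session")
def ensemble20():
    """20-matrix nestedness ensemble, 10x10, 5 modules, 20 interactions."""
    return pn.nestedness_ensemble(10, 10, 5, 20, seed=0)


@pytest.fixture(scope="session")
def community():
    """One 10x10/20-interaction system: matrix, parameters, truth network."""
    M = pn.random_matrix(10, 10, 20, seed=0, distinct_rows=True)
    params = pn.feasible_parameters(M, seed=1)
    return M, params, params.quantitative_network(M)


@pytest.fixture(scope="session")
def trajectory(community):
    """96 h / 6 min noiseless trajectory from a delta=0.5 perturbed start."""
    M, params, _ = community
    init = pn.perturbed_initial_state(params.H_star, params.V_star, 0.5, seed=2)
    return pn.integrate_and_sample(params, M, init, 6 / 1440, 4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
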