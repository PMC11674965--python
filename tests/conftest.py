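import numpy as np
import pytest

import streamconn as sc


@pytest.fixture(scope="session")
def atlas():
    return sc.load_atlas()


@pytest.fixture(scope="session")
def connections(atlas):
    return sc.enumerate_connections(atlas)


@pytest.fixture(scope="session")
def families(connections):
    return sc.connection_families(connections)


@pytest.fixture(scope="session")
def default_config():
    return sc.CohortConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return sc.generate_cohort(default_config)


@pytest.fixture(scope="session")
def var2_model(default_config):
    """A stationary bivariate VAR(2) with known coefficients (0 drives 1)."""
    coeffs = np.zeros((2, 2, 2))
    coeffs[0] = [[0.5, 0.1], [0.3, 0.4]]
    coeffs[1] = [[-0.2, 0.0], [0.05, -0.25]]
    return sc.VARModel(coeffs=coeffs, sigma=np.eye(2), fs=default_config.fs)


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast cohort used by pipeline round-trip tests."""
    return sc.CohortConfig(
        n_gamers=4, n_nongamers=4, n_runs=1, samples_per_run=150, seed=11
    )
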