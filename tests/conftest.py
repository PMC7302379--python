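import numpy as np
import pytest

from episcreen import SimulationConfig, generate_manifest, simulate_beta_matrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_genes=60, cpgs_per_gene=3)


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_beta(small_config, small_manifest):
    return simulate_beta_matrix(small_manifest, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
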