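import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from diagnet.synthetic import SimConfig, generate_expression, generate_network


@pytest.fixture(scope="session")
def small_config():
    """A compact instance: quick to simulate, still carries all structure."""
    return SimConfig(
        n_genes=120,
        module_size=12,
        n_pivotal=3,
        n_cohorts=3,
        n_tumor=30,
        n_normal=30,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_instance(small_config):
    network, truth = generate_network(small_config)
    datasets = generate_expression(network, truth, small_config)
    return network, truth, datasets


@pytest.fixture(scope="session")
def default_instance():
    """One instance at the default study conditions (400 genes, 40-gene
    module, 6 cohorts of 30+30)."""
    config = SimConfig(rng_seed=5)
    network, truth = generate_network(config)
    datasets = generate_expression(network, truth, config)
    return config, network, truth, datasets
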