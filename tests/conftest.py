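import numpy as np
import pytest

from cotwin.simulate import SimulationConfig, build_truth, simulate_twin_pairs, simulate_unrelated


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions with a powered unrelated sample."""
    return SimulationConfig(
        n_unrelated=500,
        n_causal_genes=20,
        n_reactive_genes=20,
        n_null_genes=200,
        n_cohorts=4,
        n_per_cohort=500,
        seed=11,
    )


@pytest.fixture(scope="session")
def unrelated_dataset(small_config):
    return simulate_unrelated(small_config)


@pytest.fixture(scope="session")
def twin_dataset(small_config, unrelated_dataset):
    truth = unrelated_dataset[3]
    return simulate_twin_pairs(small_config, truth)
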