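import pytest

from cerna_sponge.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation for unit tests (fast, full structure)."""
    return SimulationConfig(
        n_features=40,
        n_samples_per_group=8,
        n_de=10,
        n_triplets=5,
        n_cis_per_class=2,
        n_terms=8,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)
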