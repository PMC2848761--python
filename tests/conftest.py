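import pytest

from seedqtl import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured experiment configuration for unit tests."""
    return SimulationConfig(
        seed=1,
        n_genes=200,
        n_probesets=60,
        n_markers=12,
        library_depth_range=(20_000, 30_000),
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def default_experiment():
    """The default-scale experiment (~2000 genes, 500 probesets, 8 libraries)."""
    return simulate_experiment(SimulationConfig(seed=1))
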