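import numpy as np
import pytest

from thinktime import SimulationConfig, SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_config():
    """Fast simulator configuration for unit tests."""
    return SimulationConfig(
        c_prop=0.55, n_steps=150, n_iterations=200, n_individuals=10, seed=7
    )


@pytest.fixture(scope="session")
def small_synth_config():
    """Miniature experiment: 3 participants/group, 9 blocks of 4 trials."""
    return SynthConfig(n_per_group=3, blocks=9, trials_per_block=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_synth_config):
    return generate_dataset(small_synth_config)
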