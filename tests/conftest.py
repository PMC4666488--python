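import numpy as np
import pytest

from critrange import ModelConfig, build_weight_matrix


@pytest.fixture(scope="session")
def small_config():
    """A 20-neuron configuration, cheap enough for loop-oracle comparisons."""
    return ModelConfig(n_neurons=20, inhibitory_fraction=0.2, depression_window=5)


@pytest.fixture(scope="session")
def default_weights():
    """One default 1000-neuron weight matrix shared across tests."""
    return build_weight_matrix(ModelConfig(), seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
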