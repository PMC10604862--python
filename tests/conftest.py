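import numpy as np
import pytest

from ibceeg import IBCConfig, SynthSpec, simulate_de_features


@pytest.fixture(scope="session")
def small_de():
    """A small leading-signal dataset shared across read-only tests:
    10 channels, 5 bands, 5 blocks, 3 classes."""
    spec = SynthSpec(n_channels=10, n_epochs_per_block=60, seed=7)
    de, labels, blocks, truth = simulate_de_features(spec)
    return de, labels, blocks, truth


@pytest.fixture()
def small_config():
    return IBCConfig(k=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
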