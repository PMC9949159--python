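import numpy as np
import pytest

from axonmap.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimConfig(
        n_neurons=30, n_rolonies_per_neuron=20,
        dropout_rate=0.0, substitution_rate=0.0, jitter_sd=0.0,
        n_floating_per_soma=0, n_secondary_barcodes=0, seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_cfg):
    return simulate_dataset(noiseless_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
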