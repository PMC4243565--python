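import numpy as np
import pytest

from infomaxnet import NetworkConfig, SynapticParameters, initialize_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def net5():
    return NetworkConfig(n_neurons=5, p_max=0.95, p0=0.05)


@pytest.fixture
def params5(net5, rng):
    return initialize_network(net5, rng)


def make_params(n_rec, n_ext=0, scale=0.1, seed=0, h=None, p_max=0.95, p0=0.05):
    rng = np.random.default_rng(seed)
    w = rng.uniform(-scale, scale, (n_rec, n_rec + n_ext))
    np.fill_diagonal(w[:, :n_rec], 0.0)
    if h is None:
        h = np.log((p_max - p0) / p0)
    return SynapticParameters(w, np.full(n_rec, float(h)))
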