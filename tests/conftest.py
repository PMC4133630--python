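import numpy as np
import pytest

from dpbtn.network import Experiment, PerturbationDesign, SignalingNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_net():
    """2-node chain 1 -> 2 with the reference simulation parameters."""
    W = np.zeros((2, 2))
    W[0, 1] = 1.0
    return SignalingNetwork(W, np.full(2, -0.25), gamma=10.0)


@pytest.fixture
def small_net(rng):
    """Random 3-node network for enumeration-oracle comparisons."""
    W = rng.normal(0, 1, (3, 3))
    np.fill_diagonal(W, 0.0)
    return SignalingNetwork(W, -rng.random(3), gamma=1.5)


@pytest.fixture
def trivial_design():
    return PerturbationDesign(n_nodes=2, experiments=[Experiment(label="none")])
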