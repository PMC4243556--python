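import numpy as np
import pytest

import barrelnet as bn


@pytest.fixture(scope="session")
def small_network():
    return bn.generate_network(10, 0.10, seed=1)


@pytest.fixture(scope="session")
def tiny_protocol():
    return bn.StimulusProtocol(trials_per_whisker=30)


@pytest.fixture(scope="session")
def tiny_ensemble(small_network, tiny_protocol):
    return bn.simulate_session(small_network, tiny_protocol, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
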