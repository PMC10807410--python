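import numpy as np
import pytest

from plastinet.topology import Network


@pytest.fixture
def two_neuron_net():
    """Two excitatory neurons, one synapse 0 -> 1 with a 2 ms delay."""
    pos = np.array([[50.0, 50.0], [150.0, 50.0]])
    return Network(
        pos=pos,
        excitatory=np.array([True, True]),
        substrate=(200.0, 100.0),
        pre=np.array([0]),
        post=np.array([1]),
        w=np.array([0.5]),
        delay_ms=np.array([2.0]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
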