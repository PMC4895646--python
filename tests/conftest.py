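import pytest
from hypothesis import settings

import siglogic as sl

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_net() -> sl.SignalingNetwork:
    return sl.toy_network()


@pytest.fixture
def one_node_net() -> sl.SignalingNetwork:
    """A single receptor node, input-eligible — the minimal stimulated system."""
    return sl.SignalingNetwork(["R"], (), input_nodes=["R"])


@pytest.fixture
def chain_net() -> sl.SignalingNetwork:
    """A -> B -> C activation chain with unit weights."""
    edges = (
        sl.Edge("A", "B", sl.ACTIVATING, 1.0),
        sl.Edge("B", "C", sl.ACTIVATING, 1.0),
    )
    return sl.SignalingNetwork(["A", "B", "C"], edges, input_nodes=["A"])
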