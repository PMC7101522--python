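import pytest

from ppiscreen.graph import Network


@pytest.fixture
def path3() -> Network:
    return Network(edges=[("A", "B"), ("B", "C")])


@pytest.fixture
def star5() -> Network:
    """Star: center C over 4 leaves."""
    return Network(edges=[("C", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def triangle() -> Network:
    return Network(edges=[("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def mixed_net() -> Network:
    """5 isolated nodes + a triangle + a 4-node path."""
    net = Network(edges=[("T1", "T2"), ("T2", "T3"), ("T1", "T3"),
                         ("P1", "P2"), ("P2", "P3"), ("P3", "P4")])
    for i in range(5):
        net.add_node(f"I{i}")
    return net
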