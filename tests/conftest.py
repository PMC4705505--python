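import pytest

from slpc.network_io import ComplexSet, PPINetwork
from slpc.reliability import GOAnnotation


@pytest.fixture
def triangle() -> PPINetwork:
    return PPINetwork.from_edges([("m", "n"), ("n", "x"), ("m", "x")])


@pytest.fixture
def small_annotation() -> GOAnnotation:
    """Two specific terms shared by m and n, one broad term of size 100."""
    pairs = {("m", "G1"), ("n", "G1"), ("m", "G2"), ("n", "G2"), ("m", "G3")}
    pairs |= {(f"z{i}", "BROAD") for i in range(98)}
    pairs |= {("m", "BROAD"), ("n", "BROAD")}  # T_max = 100
    # G1 annotates 10 proteins in total, G2 twelve
    pairs |= {(f"z{i}", "G1") for i in range(8)}
    pairs |= {(f"z{i}", "G2") for i in range(10)}
    return GOAnnotation.from_pairs(pairs)


@pytest.fixture
def disjoint_gold() -> ComplexSet:
    return ComplexSet([{"a", "b", "c"}, {"d", "e", "f", "g", "h"}])
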