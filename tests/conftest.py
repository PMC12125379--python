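import pytest

from pwmod import Clustering, ProbabilisticNetwork


@pytest.fixture
def two_triangles():
    """Two disjoint triangles, all edges certain; communities = the triangles."""
    edges = {
        ("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0,
        ("d", "e"): 1.0, ("e", "f"): 1.0, ("d", "f"): 1.0,
    }
    network = ProbabilisticNetwork.from_edges(edges)
    clustering = Clustering.from_mapping(
        {n: ("t1" if n in "abc" else "t2") for n in "abcdef"}
    )
    return network, clustering


@pytest.fixture
def single_cross_edge():
    """One edge with p = 0.8 between two singleton communities: E(Q) = -0.4."""
    network = ProbabilisticNetwork.from_edges({("a", "b"): 0.8})
    clustering = Clustering.from_mapping({"a": "1", "b": "2"})
    return network, clustering

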