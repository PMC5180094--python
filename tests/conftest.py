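import pytest

from metacentrality import (
    WeightedNetwork,
    make_deterministic_si_fixture,
    make_named_graph,
)


@pytest.fixture
def triangle() -> WeightedNetwork:
    """Weighted triangle: a-b=1, b-c=2, a-c=3."""
    return WeightedNetwork([("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0)])


@pytest.fixture
def unit_path3() -> WeightedNetwork:
    """Unit-weight path v00-v01-v02 (the deterministic SI fixture)."""
    return make_deterministic_si_fixture(3)


@pytest.fixture
def star5() -> WeightedNetwork:
    """Unit-weight star with hub v00 and four leaves."""
    return make_named_graph("star", 5)


@pytest.fixture
def k4() -> WeightedNetwork:
    return make_named_graph("complete", 4)


@pytest.fixture
def toy_graphs(triangle, unit_path3, star5, k4) -> dict:
    """The small known-answer graphs used by the oracle cross-checks."""
    return {
        "triangle": triangle,
        "path3": unit_path3,
        "star5": star5,
        "k4": k4,
        "cycle6": make_named_graph("cycle", 6),
        "bipartite23": make_named_graph("complete_bipartite", 2, n2=3),
    }
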