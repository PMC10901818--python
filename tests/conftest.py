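import numpy as np
import pytest

from spreadpred import (LFRConfig, SIRConfig, UndirectedGraph, generate_lfr,
                        toy_graph)


@pytest.fixture(scope="session")
def p3():
    return toy_graph("path_3")


@pytest.fixture(scope="session")
def dyad():
    return toy_graph("dyad")


@pytest.fixture(scope="session")
def two_triangles():
    return toy_graph("two_triangles")


def random_connected_graph(rng: np.random.Generator, n: int,
                           extra_edge_prob: float = 0.08) -> UndirectedGraph:
    """Random spanning tree plus Bernoulli extra edges: connected, simple."""
    edges = [(int(rng.integers(i)), i) for i in range(1, n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < extra_edge_prob:
                edges.append((i, j))
    return UndirectedGraph.from_edges(edges, n=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fixture_graphs():
    """All fixture graphs with N <= 12 used for exhaustive oracle checks."""
    names = ["dyad", "path_3", "path_6", "cycle_6", "star_5", "star_9",
             "complete_4", "complete_5"]
    graphs = {name: toy_graph(name) for name in names}
    graphs["two_triangles"] = toy_graph("two_triangles")[0]
    rng = np.random.default_rng(7)
    for i in range(4):
        graphs[f"random_12_{i}"] = random_connected_graph(rng, 12, 0.2)
    return graphs


@pytest.fixture(scope="session")
def lfr_002():
    """One LFR network of the study suite (mu=0.02) with its partition."""
    return generate_lfr(LFRConfig(n=1000, mu=0.02, rng_seed=0))


@pytest.fixture(scope="session")
def lfr_005():
    return generate_lfr(LFRConfig(n=1000, mu=0.05, rng_seed=0))
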