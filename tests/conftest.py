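import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vocnet.io import EmissionMatrix


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint unit-weight triangles — the canonical Q = 0.5 graph."""
    g = nx.Graph()
    g.add_weighted_edges_from(
        [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
         ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
    )
    return g


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.5,
                          max_w: int = 9) -> nx.Graph:
    """Erdős–Rényi graph with random positive integer weights."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j, weight=int(rng.integers(1, max_w + 1)))
    return g


@pytest.fixture
def graph_factory():
    return random_weighted_graph


@pytest.fixture
def small_matrix() -> EmissionMatrix:
    data = pd.DataFrame(
        [[0.0, 1.5, 0.0], [2.0, 0.0, 3.0], [0.0, 0.0, 0.5], [4.0, 2.5, 0.0]],
        index=["sp1", "sp2", "sp3", "sp4"],
        columns=["PM33", "PM45", "PM59"],
    )
    return EmissionMatrix(data, family_of={f"sp{i}": "Fam" for i in range(1, 5)})
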