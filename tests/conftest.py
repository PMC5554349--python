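import numpy as np
import pytest

from bionet3d import fixtures as fix
from bionet3d.graph_core import Edge, Graph


@pytest.fixture
def barbell():
    """Two triangles joined by one bridge, with the planted partition."""
    return fix.make_barbell(3)


@pytest.fixture
def triangle():
    return fix.make_classic("cycle", 3)


@pytest.fixture
def path4():
    return fix.make_classic("path", 4)


def random_graph(rng: np.random.Generator, n: int, p: float = 0.45, weighted: bool = False) -> Graph:
    """Seeded Erdos-Renyi-style graph with at least one edge."""
    while True:
        g = Graph()
        for i in range(n):
            g.add_node(f"n{i}")
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    w = float(rng.integers(1, 5)) if weighted else 1.0
                    g.add_edge(Edge(f"n{i}", f"n{j}", w))
        if g.m >= 1:
            return g


def random_connected_graph(rng: np.random.Generator, n: int, extra_p: float = 0.3) -> Graph:
    """Random spanning tree plus extra edges: connected by construction."""
    g = Graph()
    for i in range(n):
        g.add_node(f"n{i}")
    for i in range(1, n):
        j = int(rng.integers(0, i))
        g.add_edge(Edge(f"n{j}", f"n{i}"))
    for i in range(n):
        for j in range(i + 1, n):
            if not g.has_edge(f"n{i}", f"n{j}") and rng.random() < extra_p:
                g.add_edge(Edge(f"n{i}", f"n{j}"))
    return g
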