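import numpy as np
import pytest

from multiplexshield import MultiplexGraph, build_supra_adjacency


@pytest.fixture
def tiny_graph() -> MultiplexGraph:
    """n=3, L=2 undirected fixture: layer 0 has edges (0,1),(1,2); layer 1
    has edge (0,2).  Intra-layer copy degrees: (1,2,1, 1,0,1)."""
    return MultiplexGraph(
        num_nodes=3,
        num_layers=2,
        edges=[[(0, 1, 1.0), (1, 2, 1.0)], [(0, 2, 1.0)]],
    )


@pytest.fixture
def tiny_supra(tiny_graph):
    return build_supra_adjacency(tiny_graph)


@pytest.fixture
def two_triangles() -> MultiplexGraph:
    """Single layer, 7 nodes: triangles {0,1,2} and {4,5,6} joined through
    bridge node 3 via edges (2,3) and (3,4)."""
    edges = [(0, 1), (0, 2), (1, 2), (4, 5), (4, 6), (5, 6), (2, 3), (3, 4)]
    return MultiplexGraph(
        num_nodes=7, num_layers=1,
        edges=[[(u, v, 1.0) for u, v in edges]],
    )


def dense_supra_oracle(graph: MultiplexGraph) -> np.ndarray:
    """Brute-force dense supra-adjacency assembly, independent of the
    package's sparse construction."""
    n, L = graph.num_nodes, graph.num_layers
    N = n * L
    A = np.zeros((N, N))
    for j, layer in enumerate(graph.edges):
        for u, v, w in layer:
            A[u + n * j, v + n * j] = w
            if not graph.directed:
                A[v + n * j, u + n * j] = w
    for i in range(n):
        for j in range(L):
            for jp in range(L):
                if j != jp:
                    A[i + n * j, i + n * jp] = 1.0
    return A
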