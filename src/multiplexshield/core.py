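"""Multiplex graph data model, edge-list I/O, supra-adjacency and G(n,m) generation.

A fully-aligned multiplex network has the same ``n`` nodes in each of ``L``
layers; each layer carries its own intra-layer edge set.  The supra-adjacency
matrix places the layer adjacencies on the block diagonal and couples the ``L``
copies of every node with unweighted identity blocks, so the copy of node
``i`` in layer ``j`` sits at supra index ``i + n*j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplexGraph",
    "SupraAdjacency",
    "LayerStats",
    "read_multiplex_edgelist",
    "write_multiplex_edgelist",
    "build_supra_adjacency",
    "generate_er_multiplex",
    "layer_stats",
    "degree_vector",
]

Edge = tuple[int, int, float]


@dataclass
class MultiplexGraph:
    """Node-aligned multilayer graph.

    Parameters
    ----------
    num_nodes
        Number of nodes per layer (the node set is shared by all layers).
    num_layers
        Number of layers ``L >= 1``.
    edges
        One list of ``(source, target, weight)`` tuples per layer.  Undirected
        edges are stored once, canonicalized as ``source < target``.
    directed
        Whether intra-layer edges are directed.
    """

    num_nodes: int
    num_layers: int
    edges: list[list[Edge]] = field(default_factory=list)
    directed: bool = False

    def __post_init__(self) -> None:
        if self.num_nodes < 1:
            raise ValueError("num_nodes must be >= 1")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if not self.edges:
            self.edges = [[] for _ in range(self.num_layers)]
        if len(self.edges) != self.num_layers:
            raise ValueError(
                f"edges has {len(self.edges)} layers, expected {self.num_layers}"
            )
        self.edges = [
            [self._canonical(u, v, w) for u, v, w in layer] for layer in self.edges
        ]
        self._validate()

    def _canonical(self, u: int, v: int, w: float = 1.0) -> Edge:
        u, v = int(u), int(v)
        if not self.directed and u > v:
            u, v = v, u
        return (u, v, float(w))

    def _validate(self) -> None:
        n = self.num_nodes
        for l, layer in enumerate(self.edges):
            seen: set[tuple[int, int]] = set()
            for u, v, _ in layer:
                if not (0 <= u < n and 0 <= v < n):
                    raise ValueError(f"edge ({u},{v}) out of range in layer {l}")
                if u == v:
                    raise ValueError(f"self-loop ({u},{u}) in layer {l}")
                if (u, v) in seen:
                    raise ValueError(f"duplicate edge ({u},{v}) in layer {l}")
                seen.add((u, v))

    @property
    def layer_edge_counts(self) -> list[int]:
        return [len(layer) for layer in self.edges]

    def layer_adjacency(self, layer: int) -> sp.csr_array:
        """Sparse ``n x n`` adjacency of one layer (symmetric if undirected)."""
        n = self.num_nodes
        es = self.edges[layer]
        if not es:
            return sp.csr_array((n, n))
        u, v, w = (np.asarray(x) for x in zip(*es))
        if self.directed:
            return sp.csr_array((w, (u, v)), shape=(n, n))
        return sp.csr_array(
            (np.concatenate([w, w]), (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(n, n),
        )

    def edge_sets(self) -> list[set[tuple[int, int]]]:
        """Per-layer edge sets ignoring weights (canonical orientation)."""
        return [{(u, v) for u, v, _ in layer} for layer in self.edges]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiplexGraph):
            return NotImplemented
        return (
            self.num_nodes == other.num_nodes
            and self.num_layers == other.num_layers
            and self.directed == other.directed
            and [sorted(l) for l in self.edges] == [sorted(l) for l in other.edges]
        )


@dataclass
class SupraAdjacency:
    """Supra-adjacency of a fully-aligned multiplex graph.

    ``matrix`` is ``N x N`` sparse with ``N = n*L``: diagonal blocks are the
    layer adjacencies, every off-diagonal block is the identity coupling.
    Coupling is always unweighted and bidirectional, even for directed graphs.
    """

    matrix: sp.csr_array
    num_nodes: int  # n, per layer
    num_layers: int  # L
    directed: bool = False

    def __post_init__(self) -> None:
        N = self.num_nodes * self.num_layers
        if self.matrix.shape != (N, N):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({N},{N})")
        self._binarized: sp.csr_array | None = None
        self._intra: sp.csr_array | None = None

    @property
    def num_supra_nodes(self) -> int:
        return self.num_nodes * self.num_layers

    @property
    def num_supra_edges(self) -> int:
        """Edge count: undirected edges counted once; directed intra-layer
        edges counted per direction, coupling pairs once."""
        if not self.directed:
            return self.matrix.nnz // 2
        coo = self.matrix.tocoo()
        intra = coo.row // self.num_nodes == coo.col // self.num_nodes
        n_intra = int(intra.sum())
        return n_intra + (self.matrix.nnz - n_intra) // 2

    def copy_index(self, node: int, layer: int) -> int:
        return node + self.num_nodes * layer

    def binarized(self) -> sp.csr_array:
        if self._binarized is None:
            b = self.matrix.copy()
            b.data = np.ones_like(b.data)
            self._binarized = b
        return self._binarized

    def intra_matrix(self, binarize: bool = True) -> sp.csr_array:
        """The supra matrix restricted to intra-layer (diagonal) blocks."""
        if self._intra is None:
            coo = self.matrix.tocoo()
            keep = coo.row // self.num_nodes == coo.col // self.num_nodes
            self._intra = sp.csr_array(
                (np.ones(int(keep.sum())), (coo.row[keep], coo.col[keep])),
                shape=self.matrix.shape,
            )
        return self._intra


@dataclass
class LayerStats:
    """Per-layer structural summary: edge counts, mean degrees, densities."""

    edge_counts: list[int]
    mean_degrees: list[float]
    densities: list[float]


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_multiplex_edgelist(
    path,
    directed: bool = False,
    num_nodes: int | None = None,
    num_layers: int | None = None,
) -> MultiplexGraph:
    """Read a multiplex edge list: one ``layer source target [weight]`` line
    per intra-layer edge, ``#`` comments, whitespace-delimited.

    Node and layer identifiers are re-indexed to contiguous 0-based integers
    in first-appearance order unless explicit ``num_nodes``/``num_layers``
    counts are given, in which case identifiers must already be in-range
    integers.  Self-loops are dropped and duplicate edges collapsed, with a
    logged warning.
    """
    explicit = num_nodes is not None or num_layers is not None
    node_ids: dict[str, int] = {}
    layer_ids: dict[str, int] = {}

    def node_index(tok: str, lineno: int) -> int:
        if explicit:
            i = _parse_int(tok, lineno)
            if num_nodes is not None and not (0 <= i < num_nodes):
                raise ValueError(
                    f"line {lineno}: node id {i} outside [0, {num_nodes})"
                )
            return i
        return node_ids.setdefault(tok, len(node_ids))

    def layer_index(tok: str, lineno: int) -> int:
        if explicit:
            l = _parse_int(tok, lineno)
            if num_layers is not None and not (0 <= l < num_layers):
                raise ValueError(
                    f"line {lineno}: layer id {l} outside [0, {num_layers})"
                )
            return l
        return layer_ids.setdefault(tok, len(layer_ids))

    raw: list[tuple[int, int, int, float]] = []
    max_node = -1
    max_layer = -1
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            toks = stripped.split()
            if len(toks) not in (3, 4):
                raise ValueError(
                    f"line {lineno}: expected 'layer source target [weight]', "
                    f"got {len(toks)} tokens"
                )
            l = layer_index(toks[0], lineno)
            u = node_index(toks[1], lineno)
            v = node_index(toks[2], lineno)
            if len(toks) == 4:
                try:
                    w = float(toks[3])
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: non-numeric weight {toks[3]!r}"
                    ) from None
            else:
                w = 1.0
            raw.append((l, u, v, w))
            max_node = max(max_node, u, v)
            max_layer = max(max_layer, l)

    n = num_nodes if num_nodes is not None else max_node + 1
    L = num_layers if num_layers is not None else max_layer + 1
    n = max(n, 1)
    L = max(L, 1)

    per_layer: list[dict[tuple[int, int], float]] = [dict() for _ in range(L)]
    dropped_loops = 0
    collapsed = 0
    for l, u, v, w in raw:
        if u == v:
            dropped_loops += 1
            continue
        if not directed and u > v:
            u, v = v, u
        if (u, v) in per_layer[l]:
            collapsed += 1
            continue
        per_layer[l][(u, v)] = w
    if dropped_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, dropped_loops)
    if collapsed:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, collapsed)

    edges = [[(u, v, w) for (u, v), w in layer.items()] for layer in per_layer]
    return MultiplexGraph(num_nodes=n, num_layers=L, edges=edges, directed=directed)


def _parse_int(tok: str, lineno: int) -> int:
    try:
        return int(tok)
    except ValueError:
        raise ValueError(f"line {lineno}: non-integer identifier {tok!r}") from None


def write_multiplex_edgelist(graph: MultiplexGraph, path) -> None:
    """Write ``layer source target weight`` lines, sorted by (layer, source,
    target), preceded by a header comment recording n, L and directedness."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            f"# multiplex edge list: num_nodes={graph.num_nodes} "
            f"num_layers={graph.num_layers} "
            f"directed={str(graph.directed).lower()}\n"
        )
        for l, layer in enumerate(graph.edges):
            for u, v, w in sorted(layer):
                wtxt = f"{int(w)}" if float(w).is_integer() else f"{w!r}"
                fh.write(f"{l} {u} {v} {wtxt}\n")


# ---------------------------------------------------------------------------
# Supra-adjacency
# ---------------------------------------------------------------------------

def build_supra_adjacency(graph: MultiplexGraph) -> SupraAdjacency:
    """Assemble the ``N x N`` supra-adjacency, ``N = n*L``.

    Entry ``(i+n*j, i'+n*j)`` carries the weight of intra-layer edge
    ``(i, i')`` of layer ``j``; entries ``(i+n*j, i+n*j')`` are 1 for every
    ``j != j'`` (identity coupling, bidirectional even when directed).
    """
    n, L = graph.num_nodes, graph.num_layers
    blocks = [graph.layer_adjacency(l) for l in range(L)]
    supra = sp.block_diag(blocks, format="coo")

    if L > 1:
        i = np.arange(n)
        rows, cols = [], []
        for j in range(L):
            for jp in range(L):
                if j != jp:
                    rows.append(i + n * j)
                    cols.append(i + n * jp)
        coup = sp.coo_array(
            (np.ones(n * L * (L - 1)), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n * L, n * L),
        )
        supra = supra + coup

    return SupraAdjacency(
        matrix=sp.csr_array(supra),
        num_nodes=n,
        num_layers=L,
        directed=graph.directed,
    )


def degree_vector(supra: SupraAdjacency, mode: str = "total") -> np.ndarray:
    """Unweighted degree of every node-layer copy.

    Modes: ``out`` (row counts), ``in`` (column counts), ``total`` (undirected
    degree; in+out for directed), ``intra_only`` (out-degree counting only
    intra-layer edges — the degree entering the Protection Value).
    """
    if mode == "intra_only":
        b = supra.intra_matrix()
        return np.asarray(b.sum(axis=1)).ravel()
    b = supra.binarized()
    if mode == "out":
        return np.asarray(b.sum(axis=1)).ravel()
    if mode == "in":
        return np.asarray(b.sum(axis=0)).ravel()
    if mode == "total":
        out = np.asarray(b.sum(axis=1)).ravel()
        if not supra.directed:
            return out
        return out + np.asarray(b.sum(axis=0)).ravel()
    raise ValueError(f"unknown degree mode {mode!r}")


# ---------------------------------------------------------------------------
# Erdős–Rényi G(n, m) multiplex generation
# ---------------------------------------------------------------------------

def generate_er_multiplex(
    n: int,
    m: int,
    num_layers: int,
    seed: int | np.random.SeedSequence = 0,
    directed: bool = False,
) -> MultiplexGraph:
    """Generate a multiplex graph whose layers are independent uniform
    G(n, m) samples (exactly ``m`` distinct simple edges per layer).

    Each layer draws from an independent sub-stream of the seeded generator,
    so the same ``(n, m, num_layers, seed, directed)`` always reproduces the
    same graph.  ``m`` above the simple-graph maximum is capped to a complete
    layer (logged).
    """
    if n < 1 or num_layers < 1 or m < 0:
        raise ValueError("need n >= 1, num_layers >= 1, m >= 0")
    max_m = n * (n - 1) if directed else n * (n - 1) // 2
    m_eff = min(m, max_m)
    if m_eff < m:
        logger.warning(
            "requested m=%d exceeds the simple-graph maximum %d; capped", m, max_m
        )
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    edges = [
        _sample_gnm_layer(n, m_eff, np.random.default_rng(child), directed)
        for child in ss.spawn(num_layers)
    ]
    return MultiplexGraph(num_nodes=n, num_layers=num_layers, edges=edges,
                          directed=directed)


def _sample_gnm_layer(
    n: int, m: int, rng: np.random.Generator, directed: bool
) -> list[Edge]:
    """Uniform sample of m distinct simple edges on n nodes."""
    max_m = n * (n - 1) if directed else n * (n - 1) // 2
    if m == max_m:
        u, v = np.triu_indices(n, k=1)
        if directed:
            u, v = np.concatenate([u, v]), np.concatenate([v, u])
        return [(int(a), int(b), 1.0) for a, b in zip(u, v)]
    if m > max_m // 2:
        # dense regime: permute the full pair enumeration
        u, v = np.triu_indices(n, k=1)
        if directed:
            u, v = np.concatenate([u, v]), np.concatenate([v, u])
        idx = rng.permutation(len(u))[:m]
        return [(int(u[i]), int(v[i]), 1.0) for i in idx]
    # sparse regime: rejection-sample node pairs
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:
        batch = max(256, 2 * (m - len(chosen)))
        us = rng.integers(0, n, size=batch)
        vs = rng.integers(0, n, size=batch)
        for a, b in zip(us, vs):
            if a == b:
                continue
            if not directed and a > b:
                a, b = b, a
            chosen.add((int(a), int(b)))
            if len(chosen) == m:
                break
    return [(u, v, 1.0) for u, v in sorted(chosen)]


def layer_stats(graph: MultiplexGraph) -> LayerStats:
    """Per-layer edge count, mean degree (2m/n undirected, m/n directed) and
    density m / max-possible-edges."""
    n = graph.num_nodes
    max_m = n * (n - 1) if graph.directed else n * (n - 1) // 2
    counts = graph.layer_edge_counts
    factor = 1.0 if graph.directed else 2.0
    mean_degrees = [factor * c / n for c in counts]
    densities = [c / max_m if max_m else 0.0 for c in counts]
    return LayerStats(counts, mean_degrees, densities)
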