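"""Protection Value scoring and node-selection strategies.

The Protection Value (PV) of a node-layer copy combines three signals:

* bridges — the magnitude of the copy's entry in the random-walk normalized
  Fiedler vector of the supra-adjacency (copies that separate spectral
  clusters score high);
* centers — the copy's intra-layer degree (out-degree for directed graphs);
* the layer's stochastic propagation rate beta/delta, which weights layers by
  how fast an SIS epidemic spreads on them.

Layer-wise:  PV(i + n*j) = d(i + n*j) * |mu(i + n*j)| * beta(j)/delta(j).
Node-level:  PV(i) = sum over layers j of the layer-wise PV of copy (i, j).

Positive and negative Fiedler entries are treated equally (absolute value).
The MultiplexShield strategy protects the top-k entries; under the multiplex
scheme k nodes (all copies protected together), under the layer scheme k
individual node-layer copies.  Four baselines are provided: uniform-random,
acquaintance (random neighbor of a random pick), TIM (combined degree
ranking) and SpreadingDegree (degree weighted by per-layer beta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MultiplexGraph, SupraAdjacency, build_supra_adjacency, degree_vector
from .spectral import DEFAULT_TOL, SpectralResult, fiedler_rw

logger = logging.getLogger(__name__)

__all__ = [
    "LayerRates",
    "ProtectionScores",
    "ProtectionSet",
    "default_rates",
    "protection_value_multiplex",
    "protection_value_layer",
    "multiplexshield",
    "baseline_random",
    "baseline_acquaintance",
    "baseline_tim",
    "baseline_spreading_degree",
    "STRATEGY_REGISTRY",
    "select",
]

SCHEMES = ("multiplex", "layer")

#: exponent hook for re-weighting bridges vs centers; 1 = the bare product
BRIDGE_CENTER_EXPONENT = 1.0

#: cap on acquaintance re-draws before falling back to uniform filling
AV_MAX_ATTEMPTS = 10_000


@dataclass
class LayerRates:
    """Per-layer SIS rates: infection probability beta(l) in [0,1] and
    recovery probability delta(l) in [0,1].

    delta = 0 (no recovery) is a legal simulation setting; the propagation
    ratio beta/delta is only defined — and only demanded — where a strategy
    actually uses it."""

    beta: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.beta.shape != self.delta.shape or self.beta.ndim != 1:
            raise ValueError("beta and delta must be 1-D and the same length")
        if np.any(self.beta < 0) or np.any(self.beta > 1):
            raise ValueError("beta must lie in [0, 1]")
        if np.any(self.delta < 0) or np.any(self.delta > 1):
            raise ValueError("delta must lie in [0, 1]")

    @property
    def num_layers(self) -> int:
        return len(self.beta)

    @property
    def ratio(self) -> np.ndarray:
        """Stochastic propagation rate beta/delta per layer."""
        if np.any(self.delta == 0):
            raise ValueError("beta/delta undefined: some layer has delta = 0")
        return self.beta / self.delta


def default_rates(num_layers: int) -> LayerRates:
    """Rates assigned incrementally across layers over [0.5, 0.9] for both
    beta and delta (a single layer gets 0.5)."""
    return LayerRates(
        beta=np.linspace(0.5, 0.9, num_layers),
        delta=np.linspace(0.5, 0.9, num_layers),
    )


@dataclass
class ProtectionScores:
    """PV scores: length n under the multiplex scheme, n*L under layer."""

    pv: np.ndarray
    scheme: str


@dataclass
class ProtectionSet:
    """k selected node ids (multiplex scheme) or node-layer copy ids (layer
    scheme), with the method label and optionally the scores behind them."""

    members: tuple[int, ...]
    k: int
    scheme: str
    method: str
    scores: ProtectionScores | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if len(self.members) != self.k or len(set(self.members)) != self.k:
            raise ValueError("members must be exactly k distinct ids")


def _check_scheme(scheme: str) -> None:
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")


def _pool_size(graph: MultiplexGraph, scheme: str) -> int:
    return graph.num_nodes if scheme == "multiplex" else graph.num_nodes * graph.num_layers


def _check_k(k: int, pool: int) -> None:
    if not (0 <= k <= pool):
        raise ValueError(f"budget k={k} outside [0, {pool}]")


def _check_rates(rates: LayerRates, graph: MultiplexGraph) -> None:
    if rates.num_layers != graph.num_layers:
        raise ValueError(
            f"rates cover {rates.num_layers} layers, graph has {graph.num_layers}"
        )


def _top_k(scores: np.ndarray, k: int) -> tuple[int, ...]:
    """Indices of the k largest scores, ties broken by lowest id."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return tuple(int(i) for i in sorted(order[:k]))


# ---------------------------------------------------------------------------
# Protection Value
# ---------------------------------------------------------------------------

def _pv_per_copy(
    graph: MultiplexGraph,
    spectral: SpectralResult,
    rates: LayerRates,
    supra: SupraAdjacency | None = None,
) -> np.ndarray:
    n, L = graph.num_nodes, graph.num_layers
    N = n * L
    if len(spectral.mu) != N:
        raise ValueError(
            f"Fiedler vector has length {len(spectral.mu)}, expected n*L = {N}"
        )
    _check_rates(rates, graph)
    if supra is None:
        supra = build_supra_adjacency(graph)
    d = degree_vector(supra, mode="intra_only")
    bridge = np.abs(spectral.mu) ** BRIDGE_CENTER_EXPONENT
    rate_per_copy = np.repeat(rates.ratio, n)
    return d * bridge * rate_per_copy


def protection_value_layer(
    graph: MultiplexGraph,
    spectral: SpectralResult,
    rates: LayerRates,
    supra: SupraAdjacency | None = None,
) -> ProtectionScores:
    """Layer-wise PV of every node-layer copy (length n*L vector)."""
    return ProtectionScores(pv=_pv_per_copy(graph, spectral, rates, supra),
                            scheme="layer")


def protection_value_multiplex(
    graph: MultiplexGraph,
    spectral: SpectralResult,
    rates: LayerRates,
    supra: SupraAdjacency | None = None,
) -> ProtectionScores:
    """Node-level PV (length n vector): each node's layer-wise PVs summed
    over its copies."""
    per_copy = _pv_per_copy(graph, spectral, rates, supra)
    pv = per_copy.reshape(graph.num_layers, graph.num_nodes).sum(axis=0)
    return ProtectionScores(pv=pv, scheme="multiplex")


def multiplexshield(
    graph: MultiplexGraph,
    k: int,
    scheme: str = "multiplex",
    rates: LayerRates | None = None,
    tol: float = DEFAULT_TOL,
) -> ProtectionSet:
    """Select the k highest-PV nodes (multiplex scheme) or node-layer copies
    (layer scheme); deterministic, ties broken by lowest id."""
    _check_scheme(scheme)
    _check_k(k, _pool_size(graph, scheme))
    if rates is None:
        rates = default_rates(graph.num_layers)
    supra = build_supra_adjacency(graph)
    spectral = fiedler_rw(supra.matrix, tol=tol)
    if scheme == "multiplex":
        scores = protection_value_multiplex(graph, spectral, rates, supra)
    else:
        scores = protection_value_layer(graph, spectral, rates, supra)
    return ProtectionSet(
        members=_top_k(scores.pv, k), k=k, scheme=scheme,
        method="multiplexshield", scores=scores,
    )


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def baseline_random(
    graph: MultiplexGraph, k: int, scheme: str = "multiplex",
    seed: int | np.random.SeedSequence = 0,
) -> ProtectionSet:
    """k distinct ids drawn uniformly from the scheme's candidate pool."""
    _check_scheme(scheme)
    pool = _pool_size(graph, scheme)
    _check_k(k, pool)
    rng = np.random.default_rng(seed)
    members = tuple(sorted(int(i) for i in rng.choice(pool, size=k, replace=False)))
    return ProtectionSet(members=members, k=k, scheme=scheme, method="random")


def _intra_neighbors(graph: MultiplexGraph) -> list[list[list[int]]]:
    """adj[layer][node] -> intra-layer neighbor list (out-neighbors if directed)."""
    adj: list[list[list[int]]] = [
        [[] for _ in range(graph.num_nodes)] for _ in range(graph.num_layers)
    ]
    for l, layer in enumerate(graph.edges):
        for u, v, _ in layer:
            adj[l][u].append(v)
            if not graph.directed:
                adj[l][v].append(u)
    return adj


def baseline_acquaintance(
    graph: MultiplexGraph, k: int, scheme: str = "multiplex",
    seed: int | np.random.SeedSequence = 0,
) -> ProtectionSet:
    """Acquaintance vaccination: protect random neighbors of random picks.

    Multiplex scheme: pick a node and a layer uniformly, then a uniform
    intra-layer neighbor of that node; the neighbor (node id) is protected.
    Layer scheme: pick a node-layer copy uniformly, then a uniform intra-layer
    neighbor copy.  Draws landing on isolated picks or already-selected ids
    are repeated; after a bounded number of attempts the remainder is filled
    uniformly at random (logged).
    """
    _check_scheme(scheme)
    pool = _pool_size(graph, scheme)
    _check_k(k, pool)
    rng = np.random.default_rng(seed)
    adj = _intra_neighbors(graph)
    n, L = graph.num_nodes, graph.num_layers

    selected: set[int] = set()
    attempts = 0
    while len(selected) < k and attempts < AV_MAX_ATTEMPTS:
        attempts += 1
        if scheme == "multiplex":
            i = int(rng.integers(n))
            l = int(rng.integers(L))
            neigh = adj[l][i]
            if not neigh:
                continue
            selected.add(int(neigh[rng.integers(len(neigh))]))
        else:
            c = int(rng.integers(pool))
            i, l = c % n, c // n
            neigh = adj[l][i]
            if not neigh:
                continue
            selected.add(int(neigh[rng.integers(len(neigh))]) + n * l)
    if len(selected) < k:
        logger.warning(
            "acquaintance selection exhausted %d attempts with %d/%d ids; "
            "filling the remainder uniformly at random", attempts, len(selected), k,
        )
        remaining = np.setdiff1d(np.arange(pool), np.fromiter(selected, dtype=int,
                                                              count=len(selected)))
        fill = rng.choice(remaining, size=k - len(selected), replace=False)
        selected.update(int(i) for i in fill)
    return ProtectionSet(members=tuple(sorted(selected)), k=k, scheme=scheme,
                         method="av")


def _combined_degrees(graph: MultiplexGraph) -> np.ndarray:
    """Per-copy intra-layer (out-)degree, shape (L*n,)."""
    supra = build_supra_adjacency(graph)
    return degree_vector(supra, mode="intra_only")


def baseline_tim(
    graph: MultiplexGraph, k: int, scheme: str = "multiplex"
) -> ProtectionSet:
    """Targeted immunization: rank by degree, combined across layers for the
    multiplex scheme; per-copy intra-layer degree for the layer scheme."""
    _check_scheme(scheme)
    _check_k(k, _pool_size(graph, scheme))
    d = _combined_degrees(graph)
    if scheme == "multiplex":
        scores = d.reshape(graph.num_layers, graph.num_nodes).sum(axis=0)
    else:
        scores = d
    return ProtectionSet(members=_top_k(scores, k), k=k, scheme=scheme, method="tim")


def baseline_spreading_degree(
    graph: MultiplexGraph, k: int, scheme: str = "multiplex",
    rates: LayerRates | None = None,
) -> ProtectionSet:
    """SpreadingDegree: rank by degree weighted by the layer's transmissibility
    beta, combined across layers under the multiplex scheme."""
    _check_scheme(scheme)
    _check_k(k, _pool_size(graph, scheme))
    if rates is None:
        rates = default_rates(graph.num_layers)
    _check_rates(rates, graph)
    d = _combined_degrees(graph)
    weighted = d * np.repeat(rates.beta, graph.num_nodes)
    if scheme == "multiplex":
        scores = weighted.reshape(graph.num_layers, graph.num_nodes).sum(axis=0)
    else:
        scores = weighted
    return ProtectionSet(members=_top_k(scores, k), k=k, scheme=scheme,
                         method="spreadingdegree")


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

#: strategy name -> (is_stochastic, callable)
STRATEGY_REGISTRY = {
    "multiplexshield": (False, multiplexshield),
    "random": (True, baseline_random),
    "av": (True, baseline_acquaintance),
    "tim": (False, baseline_tim),
    "spreadingdegree": (False, baseline_spreading_degree),
}


def select(
    method: str,
    graph: MultiplexGraph,
    k: int,
    scheme: str = "multiplex",
    rates: LayerRates | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ProtectionSet:
    """Uniform entry point: run the named strategy from the registry."""
    if method not in STRATEGY_REGISTRY:
        raise ValueError(
            f"unknown method {method!r}; available: {sorted(STRATEGY_REGISTRY)}"
        )
    if method == "multiplexshield":
        return multiplexshield(graph, k, scheme, rates)
    if method == "random":
        return baseline_random(graph, k, scheme, seed)
    if method == "av":
        return baseline_acquaintance(graph, k, scheme, seed)
    if method == "tim":
        return baseline_tim(graph, k, scheme)
    return baseline_spreading_degree(graph, k, scheme, rates)
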