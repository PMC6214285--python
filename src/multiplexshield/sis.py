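"""Discrete-time SIS epidemics on the protected supra-graph.

Each node-layer copy is susceptible or infected.  Per synchronous timestep,
every susceptible unprotected copy in layer j is independently exposed by each
of its currently-infected in-neighbors with the target layer's infection
probability beta(j); each infected copy recovers with probability delta(j).
Infection may cross the inter-layer coupling edges (an infected copy exposing
its sibling copies at the sibling's layer rate); this is on by default and
configurable off.

Protection removes edges: under the multiplex scheme every copy of a protected
node is isolated; under the layer scheme only the named copy is.  Protected
copies can never be infected.

A copy "survives" a run if it was never infected at any timestamp (mere
end-of-run susceptibility would be inflated by SIS recovery).  The survival
percentage is theta = 100 * eta / N over all N = n*L copies, for both schemes.

The mean-field (fully-mixed) limit of the dynamics is the logistic equation
di/dt = (beta - delta) i - beta i^2, whose endemic level is 1 - delta/beta
when beta/delta > 1 and 0 otherwise; :func:`mean_field_sis` integrates it as
an analytic cross-check on the stochastic propagation rate beta/delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .core import MultiplexGraph, SupraAdjacency, build_supra_adjacency
from .strategies import (
    STRATEGY_REGISTRY,
    LayerRates,
    ProtectionSet,
    select,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EpidemicConfig",
    "EpidemicState",
    "SimulationSummary",
    "MeanFieldTrajectory",
    "apply_protection",
    "seed_attack",
    "sis_step",
    "run_simulation",
    "monte_carlo",
    "mean_field_sis",
]

DEFAULT_HORIZON = 100


@dataclass
class EpidemicConfig:
    """Settings for one epidemic experiment.

    phi initial infections are allocated as equally as possible across layers;
    horizon T caps the number of timesteps (a run also stops early once no
    copy is infected); runs is the Monte-Carlo repetition count.
    """

    rates: LayerRates
    phi: int
    horizon: int = DEFAULT_HORIZON
    scheme: str = "multiplex"
    attack: str = "random"
    runs: int = 1
    seed: int = 0
    coupling_transmission: bool = True

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.attack not in ("random", "targeted"):
            raise ValueError("attack must be 'random' or 'targeted'")


@dataclass
class EpidemicState:
    """Per-copy epidemic state over the N = n*L supra nodes."""

    infected: np.ndarray  # bool, currently infected
    ever_infected: np.ndarray  # bool, infected at any timestamp
    protected_mask: np.ndarray  # bool, permanently uninfectable
    t: int = 0

    @classmethod
    def initial(cls, num_supra_nodes: int, protected_mask: np.ndarray) -> EpidemicState:
        return cls(
            infected=np.zeros(num_supra_nodes, dtype=bool),
            ever_infected=np.zeros(num_supra_nodes, dtype=bool),
            protected_mask=protected_mask.astype(bool).copy(),
        )


@dataclass
class SimulationSummary:
    """Outcome of one run (or a Monte-Carlo aggregate over several)."""

    survived_count: int
    survived_pct: float
    theta_ave: float
    theta_std: float
    trajectory: list[int] = field(default_factory=list)
    thetas: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MeanFieldTrajectory:
    """Fully-mixed SIS trajectory: infected fraction i(t), s(t) = 1 - i(t)."""

    times: np.ndarray
    s: np.ndarray
    i: np.ndarray


# ---------------------------------------------------------------------------
# Protection and attack
# ---------------------------------------------------------------------------

def apply_protection(
    supra: SupraAdjacency, protection: ProtectionSet, num_nodes: int | None = None
) -> tuple[SupraAdjacency, np.ndarray]:
    """Remove every edge incident to the protected copies.

    Multiplex scheme: each protected node id expands to all L of its copies;
    layer scheme: the member ids are node-layer copy ids and sibling copies
    keep their edges.  Returns the pruned supra-adjacency and the boolean
    protected mask over copies.
    """
    n = supra.num_nodes if num_nodes is None else num_nodes
    L = supra.num_layers
    N = supra.num_supra_nodes
    if protection.scheme == "multiplex":
        copies = [v + n * j for v in protection.members for j in range(L)]
    elif protection.scheme == "layer":
        copies = list(protection.members)
    else:
        raise ValueError(f"unknown scheme {protection.scheme!r}")
    mask = np.zeros(N, dtype=bool)
    if copies:
        mask[np.asarray(copies, dtype=int)] = True
        keep = sp.diags_array((~mask).astype(float))
        pruned = sp.csr_array(keep @ supra.matrix @ keep)
        pruned.eliminate_zeros()
    else:
        pruned = supra.matrix
    return (
        SupraAdjacency(matrix=pruned, num_nodes=n, num_layers=L,
                       directed=supra.directed),
        mask,
    )


def _per_layer_quota(phi: int, num_layers: int) -> list[int]:
    base, rem = divmod(phi, num_layers)
    return [base + (1 if j < rem else 0) for j in range(num_layers)]


def seed_attack(
    state: EpidemicState,
    graph: MultiplexGraph,
    phi: int,
    attack: str = "random",
    seed: int | np.random.SeedSequence = 0,
) -> EpidemicState:
    """Infect phi unprotected copies, allocated as equally as possible across
    layers (remainder to the lowest-indexed layers).

    random: uniform without replacement within each layer; targeted: the
    highest intra-layer-degree unprotected copies within each layer, ties by
    lowest id.  If a layer has fewer unprotected copies than its quota the
    shortfall spills over to subsequent layers.
    """
    n, L = graph.num_nodes, graph.num_layers
    unprotected = ~state.protected_mask
    if phi > int(unprotected.sum()):
        raise ValueError(
            f"phi={phi} exceeds the {int(unprotected.sum())} unprotected copies"
        )
    rng = np.random.default_rng(seed)
    if attack == "targeted":
        intra_deg = np.zeros(n * L)
        for l, layer in enumerate(graph.edges):
            for u, v, _ in layer:
                intra_deg[u + n * l] += 1
                if not graph.directed:
                    intra_deg[v + n * l] += 1
    quotas = _per_layer_quota(phi, L)
    carry = 0
    chosen: list[int] = []
    for j in range(L):
        want = quotas[j] + carry
        candidates = np.arange(n * j, n * (j + 1))[unprotected[n * j : n * (j + 1)]]
        take = min(want, len(candidates))
        carry = want - take
        if take == 0:
            continue
        if attack == "random":
            picked = rng.choice(candidates, size=take, replace=False)
        elif attack == "targeted":
            order = np.lexsort((candidates, -intra_deg[candidates]))
            picked = candidates[order[:take]]
        else:
            raise ValueError(f"unknown attack mode {attack!r}")
        chosen.extend(int(c) for c in picked)
    if carry:
        # spill back over earlier layers with remaining capacity
        remaining = np.setdiff1d(np.flatnonzero(unprotected),
                                 np.asarray(chosen, dtype=int))
        if attack == "random":
            extra = rng.choice(remaining, size=carry, replace=False)
        else:
            order = np.lexsort((remaining, -intra_deg[remaining]))
            extra = remaining[order[:carry]]
        chosen.extend(int(c) for c in extra)
    idx = np.asarray(chosen, dtype=int)
    state.infected[idx] = True
    state.ever_infected[idx] = True
    return state


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def sis_step(
    state: EpidemicState,
    supra: SupraAdjacency,
    rates: LayerRates,
    rng: np.random.Generator,
    coupling_transmission: bool = True,
) -> EpidemicState:
    """One synchronous SIS update from the pre-step status.

    Each susceptible unprotected copy in layer j is independently exposed by
    every currently-infected in-neighbor with probability beta(j) (coupling
    neighbors count only when coupling_transmission); each pre-step infected
    copy recovers with probability delta(j).
    """
    n = supra.num_nodes
    A = supra.binarized() if coupling_transmission else supra.intra_matrix()
    x = state.infected.astype(float)
    exposures = np.asarray(A.T @ x).ravel()  # infected in-neighbor counts

    layer_of = np.arange(supra.num_supra_nodes) // n
    beta = rates.beta[layer_of]
    delta = rates.delta[layer_of]

    p_infect = 1.0 - np.power(1.0 - beta, exposures)
    susceptible = ~state.infected & ~state.protected_mask
    new_infections = susceptible & (rng.random(len(x)) < p_infect) & (exposures > 0)
    recoveries = state.infected & (rng.random(len(x)) < delta)

    state.infected = (state.infected & ~recoveries) | new_infections
    state.ever_infected |= state.infected
    state.t += 1
    return state


def run_simulation(
    graph: MultiplexGraph,
    protection: ProtectionSet | None,
    config: EpidemicConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> SimulationSummary:
    """One full epidemic: build the supra graph, apply protection, seed the
    attack, iterate until the horizon or until no copy is infected.

    Survivors are the copies never infected at any timestamp (protected copies
    always survive); theta = 100 * eta / N with N = n*L.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed) \
        if not isinstance(seed, np.random.SeedSequence) else seed
    attack_seed, dyn_seed = ss.spawn(2)

    supra = build_supra_adjacency(graph)
    if protection is not None and protection.k > 0:
        supra, mask = apply_protection(supra, protection)
    else:
        mask = np.zeros(supra.num_supra_nodes, dtype=bool)

    state = EpidemicState.initial(supra.num_supra_nodes, mask)
    seed_attack(state, graph, config.phi, config.attack, attack_seed)

    rng = np.random.default_rng(dyn_seed)
    trajectory = [int(state.infected.sum())]
    while state.t < config.horizon and state.infected.any():
        sis_step(state, supra, config.rates, rng, config.coupling_transmission)
        trajectory.append(int(state.infected.sum()))

    N = supra.num_supra_nodes
    eta = int(np.count_nonzero(~state.ever_infected))
    theta = 100.0 * eta / N
    return SimulationSummary(
        survived_count=eta, survived_pct=theta,
        theta_ave=theta, theta_std=0.0, trajectory=trajectory,
    )


def monte_carlo(
    graph: MultiplexGraph,
    method: str,
    k: int,
    config: EpidemicConfig,
    base_seed: int | None = None,
) -> SimulationSummary:
    """Repeat strategy selection + epidemic ``config.runs`` times and report
    the mean and sample standard deviation of theta.

    Deterministic strategies (multiplexshield, tim, spreadingdegree) keep one
    fixed protected set; stochastic ones (random, av) re-draw per run.  Run r
    derives its seeds from (base_seed, r), with separate sub-streams for the
    strategy and the epidemic, so results are reproducible.
    """
    if method != "none" and method not in STRATEGY_REGISTRY:
        raise ValueError(
            f"unknown method {method!r}; available: "
            f"{sorted(STRATEGY_REGISTRY) + ['none']}"
        )
    base_seed = config.seed if base_seed is None else base_seed
    stochastic = method in STRATEGY_REGISTRY and STRATEGY_REGISTRY[method][0]

    fixed_set: ProtectionSet | None = None
    if method == "none":
        fixed_set = None
    elif not stochastic:
        fixed_set = select(method, graph, k, config.scheme, config.rates)

    thetas = np.empty(config.runs)
    last: SimulationSummary | None = None
    for r in range(config.runs):
        run_ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, r])
        strat_ss, sim_ss = run_ss.spawn(2)
        if method == "none" or not stochastic:
            protection = fixed_set
        else:
            protection = select(method, graph, k, config.scheme, config.rates,
                                seed=strat_ss)
        last = run_simulation(graph, protection, config, seed=sim_ss)
        thetas[r] = last.survived_pct

    if np.all(thetas == thetas[0]):  # exact aggregate for degenerate runs
        theta_ave, theta_std = float(thetas[0]), 0.0
    else:
        theta_ave = float(thetas.mean())
        theta_std = float(thetas.std(ddof=1))
    assert last is not None
    return SimulationSummary(
        survived_count=last.survived_count,
        survived_pct=last.survived_pct,
        theta_ave=theta_ave,
        theta_std=theta_std,
        trajectory=last.trajectory,
        thetas=thetas,
    )


# ---------------------------------------------------------------------------
# Mean-field oracle
# ---------------------------------------------------------------------------

def mean_field_sis(
    beta: float, delta: float, i0: float, T: float, dt: float = 0.1
) -> MeanFieldTrajectory:
    """Integrate the fully-mixed SIS logistic ODE
    di/dt = (beta - delta) i - beta i^2 on [0, T].

    The infected fraction tends to 1 - delta/beta when beta/delta > 1 and to
    zero otherwise (for i0 > 0).
    """
    if not (0.0 <= i0 <= 1.0):
        raise ValueError("i0 must lie in [0, 1]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    times = np.arange(0.0, T + dt / 2, dt)
    if i0 == 0.0:
        i = np.zeros_like(times)
    else:
        sol = solve_ivp(
            lambda _t, y: (beta - delta) * y - beta * y * y,
            (0.0, float(times[-1])),
            [i0],
            t_eval=times,
            rtol=1e-9,
            atol=1e-12,
        )
        i = np.clip(sol.y[0], 0.0, 1.0)
    return MeanFieldTrajectory(times=times, s=1.0 - i, i=i)
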