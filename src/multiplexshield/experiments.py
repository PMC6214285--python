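"""Evaluation harnesses: effectiveness tables and scalability timing.

run_effectiveness sweeps method x scheme x attack cells on one graph and
reports Monte-Carlo theta aggregates as a CSV; run_scalability times strategy
selection alone (not the epidemic) on synthetic G(n, m) multiplex graphs
while varying n at fixed m and m at fixed n.

Both emit self-describing CSVs: the full resolved configuration is embedded
as '#' comment lines above the header, so a results file can be re-run.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import generate_er_multiplex, layer_stats, read_multiplex_edgelist
from .sis import EpidemicConfig, monte_carlo
from .strategies import (
    STRATEGY_REGISTRY,
    LayerRates,
    default_rates,
    select,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "resolve_budget",
    "run_effectiveness",
    "run_scalability",
    "N_SWEEP_DEFAULT",
    "M_SWEEP_DEFAULT",
]

DEFAULT_METHODS = ["random", "av", "tim", "spreadingdegree", "multiplexshield"]

#: node sweep at fixed m = 10,000 edges per layer, L = 3
N_SWEEP_DEFAULT = [100, 1000, 2000, 3000, 4000, 5000, 6000]
#: edge sweep at fixed n = 1,000 nodes per layer, L = 3
M_SWEEP_DEFAULT = [1000, 2000, 10_000, 20_000, 100_000, 200_000]


@dataclass
class ExperimentConfig:
    """Resolved experiment settings (file values overridden by CLI flags)."""

    # graph source: either a path or generator parameters
    edgelist: str | None = None
    directed: bool = False
    n: int = 100
    m: int = 300
    num_layers: int = 3
    graph_seed: int = 0

    methods: list[str] = field(default_factory=lambda: list(DEFAULT_METHODS))
    schemes: list[str] = field(default_factory=lambda: ["multiplex", "layer"])
    attacks: list[str] = field(default_factory=lambda: ["random", "targeted"])

    budget_fraction: float = 0.25
    k: int | None = None  # absolute budget overrides the fraction
    phi: int | None = None  # defaults to k
    beta: list[float] | None = None
    delta: list[float] | None = None
    horizon: int = 100
    runs: int = 100
    seed: int = 0
    coupling_transmission: bool = True

    # scalability sweeps
    n_sweep: list[int] = field(default_factory=lambda: list(N_SWEEP_DEFAULT))
    m_sweep: list[int] = field(default_factory=lambda: list(M_SWEEP_DEFAULT))
    sweep_m_fixed: int = 10_000
    sweep_n_fixed: int = 1000
    k_list: list[int] = field(default_factory=lambda: [25])

    output_dir: str = "results"
    dataset: str = "synthetic-er"

    def __post_init__(self) -> None:
        if not (0.0 <= self.budget_fraction <= 1.0):
            raise ValueError("budget_fraction must lie in [0, 1]")
        unknown = [m for m in self.methods if m not in STRATEGY_REGISTRY]
        if unknown:
            raise ValueError(
                f"unknown method(s) {unknown}; registry: {sorted(STRATEGY_REGISTRY)}"
            )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def load_graph(self):
        if self.edgelist is not None:
            g = read_multiplex_edgelist(self.edgelist, directed=self.directed)
            logger.info("loaded %s: n=%d L=%d", self.edgelist, g.num_nodes,
                        g.num_layers)
            return g
        g = generate_er_multiplex(self.n, self.m, self.num_layers,
                                  seed=self.graph_seed, directed=self.directed)
        logger.info("generated ER multiplex: n=%d m=%d L=%d seed=%d",
                    self.n, self.m, self.num_layers, self.graph_seed)
        return g

    def rates_for(self, num_layers: int) -> LayerRates:
        if self.beta is None and self.delta is None:
            return default_rates(num_layers)
        beta = self.beta if self.beta is not None else list(
            np.linspace(0.5, 0.9, num_layers))
        delta = self.delta if self.delta is not None else list(
            np.linspace(0.5, 0.9, num_layers))
        return LayerRates(beta=np.asarray(beta), delta=np.asarray(delta))


def resolve_budget(config: ExperimentConfig, num_nodes: int) -> tuple[int, int]:
    """Resolve (k, phi): k = floor(budget_fraction * n) unless absolute k is
    given; phi = k unless overridden."""
    k = config.k if config.k is not None else int(config.budget_fraction * num_nodes)
    phi = config.phi if config.phi is not None else k
    return k, phi


def _write_csv(df: pd.DataFrame, path, config: ExperimentConfig) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# resolved configuration:\n")
        for key, value in sorted(dataclasses.asdict(config).items()):
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
    logger.info("wrote %s (%d rows)", path, len(df))


def run_effectiveness(
    config: ExperimentConfig, output_path=None
) -> pd.DataFrame:
    """Monte-Carlo theta for every method x scheme x attack cell.

    Columns: dataset, method, scheme, attack, theta_ave, theta_std, k, phi,
    runs, seed.  Deterministic methods keep one protected set across runs;
    stochastic ones re-draw per run.
    """
    graph = config.load_graph()
    k, phi = resolve_budget(config, graph.num_nodes)
    rates = config.rates_for(graph.num_layers)
    logger.info("effectiveness: k=%d phi=%d runs=%d", k, phi, config.runs)

    rows = []
    for scheme in config.schemes:
        for attack in config.attacks:
            epi = EpidemicConfig(
                rates=rates, phi=phi, horizon=config.horizon, scheme=scheme,
                attack=attack, runs=config.runs, seed=config.seed,
                coupling_transmission=config.coupling_transmission,
            )
            for method in config.methods:
                summary = monte_carlo(graph, method, k, epi)
                rows.append({
                    "dataset": config.dataset,
                    "method": method,
                    "scheme": scheme,
                    "attack": attack,
                    "theta_ave": summary.theta_ave,
                    "theta_std": summary.theta_std,
                    "k": k,
                    "phi": phi,
                    "runs": config.runs,
                    "seed": config.seed,
                })
                logger.info("%s/%s/%s: theta_ave=%.2f theta_std=%.2f",
                            method, scheme, attack,
                            summary.theta_ave, summary.theta_std)
    df = pd.DataFrame(rows)
    if output_path is not None:
        _write_csv(df, output_path, config)
    return df


def run_scalability(
    config: ExperimentConfig, output_path=None, schemes=None
) -> pd.DataFrame:
    """Time strategy selection on G(n, m) multiplex graphs.

    Sweep 1 fixes m per layer and varies n; sweep 2 fixes n and varies m.
    For each point and each budget k the wall-clock of the selection call
    alone is recorded together with the realized per-layer mean degree.
    """
    schemes = schemes or ["multiplex"]
    rows = []
    points = [("n_sweep", n, config.sweep_m_fixed) for n in config.n_sweep]
    points += [("m_sweep", config.sweep_n_fixed, m) for m in config.m_sweep]
    for sweep, n, m in points:
        graph = generate_er_multiplex(n, m, config.num_layers,
                                      seed=config.graph_seed)
        stats = layer_stats(graph)
        mean_degree = float(np.mean(stats.mean_degrees))
        rates = config.rates_for(graph.num_layers)
        for scheme in schemes:
            for k in config.k_list:
                k_eff = min(k, n if scheme == "multiplex" else n * graph.num_layers)
                start = time.perf_counter()
                select("multiplexshield", graph, k_eff, scheme, rates)
                elapsed = time.perf_counter() - start
                rows.append({
                    "sweep": sweep, "n": n, "m": m,
                    "num_layers": config.num_layers, "scheme": scheme,
                    "k": k_eff, "mean_degree": round(mean_degree, 2),
                    "seconds": elapsed,
                })
                logger.info("%s n=%d m=%d k=%d scheme=%s: %.3fs "
                            "(mean degree %.2f)", sweep, n, m, k_eff, scheme,
                            elapsed, mean_degree)
    df = pd.DataFrame(rows)
    if output_path is not None:
        _write_csv(df, output_path, config)
    return df
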