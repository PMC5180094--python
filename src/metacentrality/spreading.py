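"""Discrete-time weighted SI / SIR simulation and spreading power.

The transmission model: a susceptible node *i* with infected neighbours
``N_i(t)`` becomes infected in one synchronous time step with probability

    p_i(t) = 1 - prod_{j in N_i(t)} (1 - (w_ij / w_M)^alpha)

where ``w_M`` is the largest edge weight in the network and ``alpha > 0``
is the infection power. Each infected neighbour is an independent Bernoulli
transmission channel whose success probability is its relative edge weight
raised to ``alpha``; with ``alpha = 1`` the epidemic is driven purely by
the weights, which is the setting used for super-spreader ground truth.

The spreading power of a seed is the mean (over independent runs) of the
mean per-step infection ratio of each run, recorded from the first step
until full coverage. Fast spreaders keep the ratio high early, so higher
index means stronger spreader. The descending ranking of the per-seed index
is the simulation ground truth against which centrality predictors are
scored.

Implementation notes: state updates are synchronous against the pre-step
infected set, realised incrementally — each susceptible node carries the
cumulative log-survival over its infected neighbours, updated only for
newly infected nodes, so one run costs O(n * coverage) array work. RNG
streams are keyed by ``(seed, seed-node index, run index)``, making the
ground-truth table independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import WeightedNetwork
from .ranking import Ranking, rank_nodes

__all__ = [
    "SimulationConfig",
    "RunTrace",
    "SpreadingPowerTable",
    "infection_probability",
    "run_si",
    "spreading_power",
    "ground_truth_ranking",
    "run_sir_ground_truth",
]

_STEP_CAP = 10**6


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of a simulation batch.

    alpha: infection power (1 binds spreading purely to the weights).
    n_runs: Monte-Carlo batch size per seed node.
    model: "SI" or "SIR".
    recovery_prob: per-step recovery probability (SIR only, must be > 0).
    seed: master RNG seed.
    """

    alpha: float = 1.0
    n_runs: int = 100
    model: str = "SI"
    recovery_prob: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.model not in ("SI", "SIR"):
            raise ValueError("model must be 'SI' or 'SIR'")
        if self.model == "SIR":
            if self.recovery_prob is None:
                raise ValueError("SIR requires recovery_prob")
            if self.recovery_prob == 0:
                raise ValueError(
                    "recovery_prob = 0 degenerates SIR to SI with no recovered "
                    "nodes; use model='SI' instead"
                )
            if not 0 < self.recovery_prob <= 1:
                raise ValueError("recovery_prob must be in (0, 1]")
        elif self.recovery_prob is not None:
            raise ValueError("recovery_prob is only meaningful for SIR")


@dataclass(frozen=True)
class RunTrace:
    """Per-step infection ratios of one run (recorded after each step)."""

    ratios: tuple[float, ...]
    steps_to_coverage: int

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))


@dataclass(frozen=True)
class SpreadingPowerTable:
    """Per-seed spreading power and the derived ground-truth ranking."""

    index: Mapping[str, float]
    ranking: Ranking = field(compare=False)

    @classmethod
    def from_index(cls, index: Mapping[str, float]) -> "SpreadingPowerTable":
        return cls(index=dict(index), ranking=rank_nodes(index, source="simulation"))


def infection_probability(
    infected_neighbor_weights: list[float], w_max: float, alpha: float = 1.0
) -> float:
    """Probability a susceptible node is infected in one step."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    survival = 1.0
    for w in infected_neighbor_weights:
        if w > w_max:
            raise ValueError(f"edge weight {w} exceeds the network maximum {w_max}")
        survival *= 1.0 - (w / w_max) ** alpha
    return 1.0 - survival


class _SimArrays:
    """Node-indexed adjacency in array form, shared across runs."""

    def __init__(self, network: WeightedNetwork, alpha: float) -> None:
        self.nodes = network.nodes
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        # log-survival per edge: log(1 - (w/w_max)^alpha); -inf when w == w_max
        self.neigh: list[np.ndarray] = []
        self.logsurv: list[np.ndarray] = []
        with np.errstate(divide="ignore"):
            for node in self.nodes:
                nbrs = network.neighbors(node)
                idx = np.array([self.index[m] for m in nbrs], dtype=np.intp)
                p = (
                    np.array([network.weight(node, m) for m in nbrs]) / network.w_max
                ) ** alpha
                self.neigh.append(idx)
                self.logsurv.append(np.log1p(-np.minimum(p, 1.0)))


def _si_run(arrays: _SimArrays, seed_idx: int, rng: np.random.Generator) -> list[float]:
    """One SI run; returns the per-step infection ratios until coverage."""
    n = arrays.n
    infected = np.zeros(n, dtype=bool)
    infected[seed_idx] = True
    # cumulative log-survival of each susceptible node w.r.t. infected set
    logsurv = np.zeros(n)
    new = np.array([seed_idx], dtype=np.intp)
    n_infected = 1
    ratios: list[float] = []
    for _ in range(_STEP_CAP):
        for j in new:
            logsurv[arrays.neigh[j]] += arrays.logsurv[j]
        susceptible = np.flatnonzero(~infected)
        p = -np.expm1(logsurv[susceptible])
        hit = susceptible[rng.random(susceptible.size) < p]
        infected[hit] = True
        n_infected += hit.size
        new = hit
        ratios.append(n_infected / n)
        if n_infected == n:
            return ratios
    raise RuntimeError(f"SI run exceeded the step cap of {_STEP_CAP}")


def run_si(
    network: WeightedNetwork, seed_node: str, config: SimulationConfig, run_index: int = 0
) -> RunTrace:
    """One SI realization from *seed_node* under *config*."""
    if config.model != "SI":
        raise ValueError("run_si requires model='SI'")
    if seed_node not in network:
        raise ValueError(f"seed node {seed_node!r} not in network")
    arrays = _SimArrays(network, config.alpha)
    seed_idx = arrays.index[seed_node]
    rng = np.random.default_rng([config.seed, seed_idx, run_index])
    ratios = _si_run(arrays, seed_idx, rng)
    return RunTrace(ratios=tuple(ratios), steps_to_coverage=len(ratios))


def spreading_power(
    network: WeightedNetwork,
    seed_node: str,
    config: SimulationConfig,
    _arrays: _SimArrays | None = None,
) -> float:
    """Mean over runs of the mean per-step infection ratio."""
    arrays = _arrays if _arrays is not None else _SimArrays(network, config.alpha)
    seed_idx = arrays.index[seed_node]
    means = []
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.seed, seed_idx, run])
        ratios = _si_run(arrays, seed_idx, rng)
        means.append(sum(ratios) / len(ratios))
    return float(np.mean(means))


def ground_truth_ranking(
    network: WeightedNetwork, config: SimulationConfig
) -> SpreadingPowerTable:
    """Spreading power of every node as seed, plus the descending ranking."""
    if config.model == "SIR":
        return run_sir_ground_truth(network, config)
    arrays = _SimArrays(network, config.alpha)
    index = {
        node: spreading_power(network, node, config, _arrays=arrays)
        for node in arrays.nodes
    }
    return SpreadingPowerTable.from_index(index)


def _sir_run(
    arrays: _SimArrays,
    seed_idx: int,
    recovery_prob: float,
    rng: np.random.Generator,
) -> int:
    """One SIR run; returns the final number of recovered nodes.

    Each step: the pre-step infected set transmits (same rule as SI), then
    each of those transmitters recovers independently with recovery_prob.
    """
    n = arrays.n
    state = np.zeros(n, dtype=np.int8)  # 0=S, 1=I, 2=R
    state[seed_idx] = 1
    for _ in range(_STEP_CAP):
        infected = np.flatnonzero(state == 1)
        if infected.size == 0:
            return int(np.count_nonzero(state == 2))
        logsurv = np.zeros(n)
        for j in infected:
            logsurv[arrays.neigh[j]] += arrays.logsurv[j]
        susceptible = np.flatnonzero(state == 0)
        p = -np.expm1(logsurv[susceptible])
        hit = susceptible[rng.random(susceptible.size) < p]
        state[hit] = 1
        recover = infected[rng.random(infected.size) < recovery_prob]
        state[recover] = 2
    raise RuntimeError(f"SIR run exceeded the step cap of {_STEP_CAP}")


def run_sir_ground_truth(
    network: WeightedNetwork, config: SimulationConfig
) -> SpreadingPowerTable:
    """Per-seed mean final recovered count over the run batch."""
    if config.model != "SIR":
        raise ValueError("run_sir_ground_truth requires model='SIR'")
    assert config.recovery_prob is not None
    arrays = _SimArrays(network, config.alpha)
    index: dict[str, float] = {}
    for node in arrays.nodes:
        seed_idx = arrays.index[node]
        totals = []
        for run in range(config.n_runs):
            rng = np.random.default_rng([config.seed, seed_idx, run])
            totals.append(_sir_run(arrays, seed_idx, config.recovery_prob, rng))
        index[node] = float(np.mean(totals))
    return SpreadingPowerTable.from_index(index)
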