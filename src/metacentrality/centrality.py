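"""The eight node-scoring measures used as aggregation inputs.

Degree and k-shell are deliberately unweighted (they contribute purely
topological opinions); the remaining six use the edge weights:

========  =======================================================
tag       measure
========  =======================================================
``C_D``   degree (edge count)
``C_S``   strength (sum of incident weights)
``C_C``   weighted closeness, edge length 1/w
``C_E``   eigenvector centrality of the weight matrix
``C_P``   weighted PageRank
``C_K``   k-shell (core number)
``C_KW``  weighted k-shell, composite degree round(sqrt(k*s))
``C_EX``  expected force, 2 transmission events, weighted force
========  =======================================================

Each measure returns a :class:`ScoreVector`; :func:`rank_nodes` turns score
vectors into tie-averaged descending rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import networkx as nx
import numpy as np

from .network import WeightedNetwork
from .ranking import Ranking, rank_nodes

__all__ = [
    "MEASURES",
    "ScoreVector",
    "degree",
    "strength",
    "closeness_weighted",
    "eigenvector_weighted",
    "pagerank_weighted",
    "kshell",
    "kshell_weighted",
    "expected_force",
    "compute_measure",
    "compute_rankings",
    "rank_nodes",
]


@dataclass(frozen=True)
class ScoreVector:
    measure: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        for n, v in self.scores.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite score {v} for node {n!r}")

    def to_ranking(self) -> Ranking:
        return rank_nodes(self.scores, source=self.measure)


def degree(network: WeightedNetwork) -> ScoreVector:
    """Unweighted degree: the number of incident edges."""
    return ScoreVector("C_D", {n: float(d) for n, d in network.graph.degree()})


def strength(network: WeightedNetwork) -> ScoreVector:
    """Weighted degree: the sum of incident edge weights."""
    return ScoreVector(
        "C_S", {n: float(s) for n, s in network.graph.degree(weight="weight")}
    )


def closeness_weighted(network: WeightedNetwork) -> ScoreVector:
    """Closeness (n-1)/sum_j d(i,j) with edge length 1/w.

    Heavier edges are shorter: weight is read as connection strength.
    """
    g = network.graph.copy()
    for u, v, w in g.edges(data="weight"):
        g[u][v]["length"] = 1.0 / w
    scores = nx.closeness_centrality(g, distance="length")
    return ScoreVector("C_C", {n: float(s) for n, s in scores.items()})


def eigenvector_weighted(
    network: WeightedNetwork, max_iter: int = 1000, tol: float = 1e-10
) -> ScoreVector:
    """Principal eigenvector of the weight matrix, unit Euclidean norm."""
    try:
        scores = nx.eigenvector_centrality(
            network.graph, max_iter=max_iter, tol=tol, weight="weight"
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"eigenvector power iteration failed to converge in {max_iter} iterations"
        ) from exc
    return ScoreVector("C_E", {n: float(s) for n, s in scores.items()})


def pagerank_weighted(
    network: WeightedNetwork,
    damping: float = 0.85,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> ScoreVector:
    """Stationary distribution of the weighted teleporting random walk."""
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    try:
        scores = nx.pagerank(
            network.graph, alpha=damping, weight="weight", max_iter=max_iter, tol=tol
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"pagerank failed to converge in {max_iter} iterations"
        ) from exc
    return ScoreVector("C_P", {n: float(s) for n, s in scores.items()})


def kshell(network: WeightedNetwork) -> ScoreVector:
    """Shell index from iterative degree pruning (the core number)."""
    return ScoreVector(
        "C_K", {n: float(c) for n, c in nx.core_number(network.graph).items()}
    )


def _round_half_up(x: float) -> int:
    # avoid banker's rounding: round(2.5) must be 3 here
    return int(math.floor(x + 0.5))


def kshell_weighted(network: WeightedNetwork) -> ScoreVector:
    """Weighted shell index via pruning on the composite degree.

    The composite degree of a surviving node is round(sqrt(k*s)) where k is
    its current (residual) degree and s its current strength; both are
    recomputed after every removal cascade. Nodes removed while the pruning
    threshold is ``k`` get shell index ``k``. On unit-weight graphs the
    composite degree equals the degree and the result matches :func:`kshell`.
    """
    g = network.graph.copy()
    shell: dict[str, float] = {}
    k = 1
    while g.number_of_nodes() > 0:
        removed_any = True
        while removed_any:
            composite = {
                n: _round_half_up(math.sqrt(g.degree(n) * g.degree(n, weight="weight")))
                for n in g.nodes
            }
            to_remove = sorted(n for n, c in composite.items() if c <= k)
            removed_any = bool(to_remove)
            for n in to_remove:
                shell[n] = float(k)
                g.remove_node(n)
        k += 1
    return ScoreVector("C_KW", shell)


def expected_force(network: WeightedNetwork) -> ScoreVector:
    """Expected force: entropy of normalized cluster force after 2 events.

    From seed ``i``, every ordered sequence of exactly two transmission
    events is enumerated (each event infects one susceptible neighbour of
    the current infected cluster). The resulting 3-node cluster has force
    ``d`` equal to the total weight on edges leaving the cluster. Forces are
    normalized over all enumerated sequences (clusters reachable by several
    orders count once per order) and the score is the Shannon entropy
    ``-sum d_bar * ln d_bar`` of that distribution.
    """
    if network.n_nodes < 4:
        raise ValueError(
            "expected force needs at least 4 nodes: on smaller networks every "
            "2-event cluster covers the graph and has zero outgoing force"
        )
    g = network.graph
    scores: dict[str, float] = {}
    for seed in network.nodes:
        forces: list[float] = []
        for first in g.neighbors(seed):
            cluster = {seed, first}
            frontier = {
                nb for c in cluster for nb in g.neighbors(c) if nb not in cluster
            }
            for second in frontier:
                final = cluster | {second}
                d = sum(
                    w
                    for c in final
                    for _, nb, w in g.edges(c, data="weight")
                    if nb not in final
                )
                forces.append(d)
        total = sum(forces)
        if total <= 0:
            raise ValueError(
                f"seed {seed!r}: all enumerated clusters have zero outgoing force; "
                "the network is too small for the expected-force measure"
            )
        ent = 0.0
        for d in forces:
            if d > 0:
                p = d / total
                ent -= p * math.log(p)
        scores[seed] = ent
    return ScoreVector("C_EX", scores)


MEASURES: dict[str, Callable[[WeightedNetwork], ScoreVector]] = {
    "C_D": degree,
    "C_S": strength,
    "C_C": closeness_weighted,
    "C_E": eigenvector_weighted,
    "C_P": pagerank_weighted,
    "C_K": kshell,
    "C_KW": kshell_weighted,
    "C_EX": expected_force,
}


def compute_measure(network: WeightedNetwork, measure: str) -> ScoreVector:
    try:
        fn = MEASURES[measure]
    except KeyError:
        raise ValueError(
            f"unknown measure {measure!r}; choose from {sorted(MEASURES)}"
        ) from None
    return fn(network)


def compute_rankings(
    network: WeightedNetwork, measures: list[str] | None = None
) -> dict[str, Ranking]:
    """Rankings for the requested measures (all eight by default)."""
    measures = list(MEASURES) if measures is None else measures
    return {m: compute_measure(network, m).to_ranking() for m in measures}
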