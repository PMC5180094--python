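"""Synthetic network generators with controllable spectral signatures.

Two tiers:

* deterministic named graphs (path, star, cycle, complete, complete
  bipartite) whose centralities, spreading behaviour and spectra are known in
  closed form — the package's known-answer fixtures;
* random families whose normalized-Laplacian spectra carry the three classic
  signatures: ``community`` (planted blocks, eigenvalues near 0),
  ``bipartite_like`` (nearly two-colourable, eigenvalues near 2) and
  ``motif_duplication`` (grown by node duplication, eigenvalue mass near 1),
  plus plain ``er_weighted`` and ``ba_weighted`` baselines.

All stochastic generators take an explicit integer seed and are
reproducible: the same spec yields the same network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .network import WeightedNetwork

__all__ = [
    "FixtureSpec",
    "make_named_graph",
    "make_random_network",
    "make_deterministic_si_fixture",
    "NAMED_FAMILIES",
    "RANDOM_FAMILIES",
]

NAMED_FAMILIES = ("path", "star", "cycle", "complete", "complete_bipartite")
RANDOM_FAMILIES = (
    "er_weighted",
    "ba_weighted",
    "community",
    "bipartite_like",
    "motif_duplication",
)

#: default edge-weight range for random families; wide enough that w/w_max
#: spreads transmission probabilities over a useful dynamic range.
DEFAULT_WEIGHT_RANGE = (0.1, 1.0)

_MAX_CONNECT_RETRIES = 200


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic network instance."""

    family: str
    n: int
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.family not in NAMED_FAMILIES + RANDOM_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


def _node_name(i: int, width: int) -> str:
    return f"v{i:0{width}d}"


def _relabel(g: nx.Graph) -> nx.Graph:
    """Zero-padded string ids so lexicographic order equals numeric order."""
    width = max(2, len(str(g.number_of_nodes() - 1)))
    mapping = {u: _node_name(i, width) for i, u in enumerate(sorted(g.nodes))}
    return nx.relabel_nodes(g, mapping)


def make_named_graph(
    family: str, n: int, weight: float | str = "unit", n2: int | None = None
) -> WeightedNetwork:
    """Deterministic toy graph with uniform edge weights.

    For ``complete_bipartite``, *n* and *n2* are the two side sizes
    (both must be >= 1).
    """
    w = 1.0 if weight == "unit" else float(weight)
    if family == "path":
        g = nx.path_graph(n)
    elif family == "star":
        # star_graph(k) has k+1 nodes; n is the total node count
        if n < 2:
            raise ValueError("star needs n >= 2")
        g = nx.star_graph(n - 1)
    elif family == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        g = nx.cycle_graph(n)
    elif family == "complete":
        g = nx.complete_graph(n)
    elif family == "complete_bipartite":
        if n2 is None:
            raise ValueError("complete_bipartite needs both side sizes (n, n2)")
        if n < 1 or n2 < 1:
            raise ValueError("complete_bipartite needs both sides >= 1")
        g = nx.complete_bipartite_graph(n, n2)
    else:
        raise ValueError(f"unknown named family {family!r}")
    g = _relabel(g)
    return WeightedNetwork((u, v, w) for u, v in g.edges())


def make_deterministic_si_fixture(n: int) -> WeightedNetwork:
    """Path graph with all weights equal.

    Every edge then has weight equal to the maximum, so SI with infection
    power 1 transmits with probability one on every edge: the epidemic is a
    deterministic breadth-first wave, which pins the simulator exactly.
    """
    if n < 3:
        raise ValueError("deterministic SI fixture needs n >= 3")
    return make_named_graph("path", n)


def _random_weights(g: nx.Graph, rng: np.random.Generator, lo: float, hi: float) -> None:
    for u, v in sorted(g.edges()):
        g[u][v]["weight"] = float(rng.uniform(lo, hi))


def _er_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def make_random_network(spec: FixtureSpec) -> WeightedNetwork:
    """Generate a connected weighted network from a :class:`FixtureSpec`.

    Retries with a perturbed substream until the sampled graph is connected;
    gives up after a bounded number of attempts with a hint to raise the
    density.
    """
    if spec.family not in RANDOM_FAMILIES:
        raise ValueError(f"{spec.family!r} is not a random family; use make_named_graph")
    lo, hi = spec.params.get("weight_range", DEFAULT_WEIGHT_RANGE)
    for attempt in range(_MAX_CONNECT_RETRIES):
        rng = np.random.default_rng([spec.seed, attempt])
        g = _sample_topology(spec, rng)
        if g.number_of_nodes() == spec.n and g.number_of_edges() > 0 and nx.is_connected(g):
            if spec.family != "motif_duplication":  # duplication sets weights itself
                _random_weights(g, rng, lo, hi)
            g = _relabel(g)
            return WeightedNetwork((u, v, d["weight"]) for u, v, d in g.edges(data=True))
    raise RuntimeError(
        f"could not generate a connected {spec.family!r} network in "
        f"{_MAX_CONNECT_RETRIES} attempts; increase the edge density parameters"
    )


def _sample_topology(spec: FixtureSpec, rng: np.random.Generator) -> nx.Graph:
    n, params = spec.n, spec.params
    if spec.family == "er_weighted":
        return _er_graph(n, params.get("p", 0.1), rng)
    if spec.family == "ba_weighted":
        m = params.get("m", 2)
        return nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    if spec.family == "community":
        blocks = params.get("blocks", 3)
        p_in = params.get("p_in", 0.3)
        p_out = params.get("p_out", 0.01)
        sizes = [n // blocks + (1 if i < n % blocks else 0) for i in range(blocks)]
        return nx.stochastic_block_model(
            sizes,
            [[p_in if i == j else p_out for j in range(blocks)] for i in range(blocks)],
            seed=int(rng.integers(2**31)),
        )
    if spec.family == "bipartite_like":
        p_across = params.get("p_across", 0.2)
        noise_frac = params.get("noise_frac", 0.03)  # share of within-side edges
        half = n // 2
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(half):
            for j in range(half, n):
                if rng.random() < p_across:
                    g.add_edge(i, j)
        # a few within-side edges so the graph is only *nearly* bipartite
        n_noise = int(noise_frac * g.number_of_edges())
        sides = [list(range(half)), list(range(half, n))]
        added = 0
        while added < n_noise:
            side = sides[int(rng.integers(2))]
            i, j = rng.choice(side, size=2, replace=False)
            if not g.has_edge(int(i), int(j)):
                g.add_edge(int(i), int(j))
                added += 1
        return g
    if spec.family == "motif_duplication":
        return _duplication_graph(n, params, rng)
    raise AssertionError(spec.family)


def _duplication_graph(n: int, params: dict[str, Any], rng: np.random.Generator) -> nx.Graph:
    """Grow by repeated node duplication.

    Each step copies a random existing node, inherits its edges with weights
    perturbed multiplicatively by uniform [0.9, 1.1], and links the copy to
    its original. Duplicated neighbourhoods create near-identical rows in the
    weight matrix, which piles normalized-Laplacian eigenvalues near 1.
    """
    lo, hi = params.get("weight_range", DEFAULT_WEIGHT_RANGE)
    seed_size = params.get("seed_size", 4)
    g = nx.complete_graph(min(seed_size, n))
    _random_weights(g, rng, lo, hi)
    next_id = g.number_of_nodes()
    while g.number_of_nodes() < n:
        template = int(rng.choice(sorted(g.nodes)))
        new = next_id
        next_id += 1
        g.add_node(new)
        for nb in sorted(g.neighbors(template)):
            w = g[template][nb]["weight"] * rng.uniform(0.9, 1.1)
            g.add_edge(new, nb, weight=float(w))
        g.add_edge(new, template, weight=float(rng.uniform(lo, hi)))
    return g
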