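"""Validated weighted-network container.

The whole pipeline operates on undirected, connected, positively weighted
graphs with no self-loops. :class:`WeightedNetwork` wraps a
:class:`networkx.Graph` and enforces those invariants once, at construction,
so downstream modules (centrality, spreading, spectrum) can assume them.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["NetworkValidationError", "WeightedNetwork"]


class NetworkValidationError(ValueError):
    """An input graph violates the weighted-network invariants."""


class WeightedNetwork:
    """An undirected, connected graph with strictly positive edge weights.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, weight)`` triples. Node identifiers are treated
        as opaque strings; all deterministic tie-breaks downstream use
        lexicographic order of these ids.
    keep_largest_component
        If the edge set describes a disconnected graph, retain the largest
        connected component (logging how many nodes were dropped) instead of
        raising. Ties between equal-sized components are broken by the
        lexicographically smallest member node.

    Raises
    ------
    NetworkValidationError
        On self-loops, duplicate undirected edges, or non-positive /
        non-finite weights.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]],
        *,
        keep_largest_component: bool = True,
    ) -> None:
        g = nx.Graph()
        for u, v, w in edges:
            u, v = str(u), str(v)
            if u == v:
                raise NetworkValidationError(f"self-loop on node {u!r} is not allowed")
            w = float(w)
            if not math.isfinite(w) or w <= 0:
                raise NetworkValidationError(
                    f"edge ({u!r}, {v!r}) has non-positive or non-finite weight {w}"
                )
            if g.has_edge(u, v):
                raise NetworkValidationError(
                    f"duplicate undirected edge ({u!r}, {v!r}); "
                    "aggregating duplicates silently would change the maximum weight"
                )
            g.add_edge(u, v, weight=w)
        if g.number_of_nodes() < 2:
            raise NetworkValidationError("a network needs at least 2 nodes and 1 edge")
        if not nx.is_connected(g):
            if not keep_largest_component:
                raise NetworkValidationError("graph is disconnected")
            components = sorted(
                nx.connected_components(g), key=lambda c: (-len(c), min(c))
            )
            dropped = g.number_of_nodes() - len(components[0])
            g = g.subgraph(components[0]).copy()
            logger.warning(
                "input graph was disconnected: %d nodes dropped, largest component retained",
                dropped,
            )
        self.graph: nx.Graph = g
        self.w_max: float = max(w for _, _, w in g.edges(data="weight"))

    # -- basic protocol ----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node ids in lexicographic order (the canonical ordering)."""
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges as ``(u, v, weight)`` with u < v, sorted."""
        for u, v, w in sorted(
            (min(a, b), max(a, b), w) for a, b, w in self.graph.edges(data="weight")
        ):
            yield u, v, w

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def neighbors(self, u: str) -> list[str]:
        return sorted(self.graph.neighbors(u))

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return list(self.edges()) == list(other.edges())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges}, "
            f"w_max={self.w_max:g})"
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_graph(cls, g: nx.Graph, weight_attr: str = "weight") -> "WeightedNetwork":
        """Build from a networkx graph; missing weights default to 1."""
        if g.is_directed():
            raise NetworkValidationError("directed input is unsupported")
        return cls(
            (u, v, data.get(weight_attr, 1.0)) for u, v, data in g.edges(data=True)
        )

    @classmethod
    def from_weights(cls, weights: Mapping[tuple[str, str], float]) -> "WeightedNetwork":
        return cls((u, v, w) for (u, v), w in weights.items())
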