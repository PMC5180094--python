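"""Node rankings with the average-position tie convention.

A ranking orders nodes by descending score. Tied scores share the average of
the positions they span (so positions always sum to n(n+1)/2), which keeps
them consistent with tie-aware Spearman correlation and tie-friendly Borda
counting downstream. The list order within a tie block is lexicographic by
node id, giving every ranking a deterministic linear order as well.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata

__all__ = ["Ranking", "rank_nodes"]


class Ranking:
    """An ordered node list with scores and tie-averaged positions.

    Attributes
    ----------
    order
        Nodes in descending score order; ties broken lexicographically.
    scores
        Node -> raw score.
    positions
        Node -> 1-based position; tied nodes share the average of the
        positions their block spans.
    source
        Provenance tag, e.g. a centrality measure name, ``"simulation"`` or
        ``"aggregated"``.
    """

    __slots__ = ("order", "scores", "positions", "source")

    def __init__(
        self,
        order: Iterable[str],
        scores: Mapping[str, float],
        positions: Mapping[str, float],
        source: str = "",
    ) -> None:
        self.order: tuple[str, ...] = tuple(order)
        self.scores: dict[str, float] = {n: float(s) for n, s in scores.items()}
        self.positions: dict[str, float] = {n: float(p) for n, p in positions.items()}
        self.source = source
        if set(self.order) != set(self.scores) or set(self.order) != set(self.positions):
            raise ValueError("order, scores and positions must cover the same node set")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.order)

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> list[str]:
        """The first *k* nodes in the deterministic linear order."""
        return list(self.order[:k])

    def position_of(self, node: str) -> float:
        return self.positions[node]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ranking):
            return NotImplemented
        return (
            self.order == other.order
            and self.positions == other.positions
            and all(
                math.isclose(
                    self.scores[n], other.scores[n], rel_tol=1e-12, abs_tol=1e-12
                )
                for n in self.order
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        head = ", ".join(self.order[:5])
        return f"Ranking(source={self.source!r}, n={len(self)}, top=[{head}...])"


def rank_nodes(scores: Mapping[str, float], source: str = "") -> Ranking:
    """Convert a score vector into a descending :class:`Ranking`.

    Tied scores receive the average of the positions they span; the linear
    order within ties is lexicographic by node id.
    """
    nodes = sorted(scores)
    values = np.array([float(scores[n]) for n in nodes])
    if not np.all(np.isfinite(values)):
        bad = [n for n, v in zip(nodes, values) if not math.isfinite(v)]
        raise ValueError(f"non-finite scores for nodes: {bad}")
    # rankdata ranks ascending; negate for descending positions.
    positions = rankdata(-values, method="average")
    order = sorted(nodes, key=lambda n: (-scores[n], n))
    return Ranking(
        order=order,
        scores={n: float(scores[n]) for n in nodes},
        positions={n: float(p) for n, p in zip(nodes, positions)},
        source=source,
    )
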