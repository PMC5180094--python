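"""Entropy-guided modified Borda count ("meta-centrality").

Plain Borda counting treats every input ranking as an equally reliable
expert. The modification implemented here first measures pairwise agreement
between the input rankings (tie-aware Spearman correlation, negatives
clipped to zero), then — for every ranking *i* — slices out the experts
that agree strongly with it (correlation >= t_b), those that disagree or
are unrelated (<= t_s), and the union of both. Rankings with middling
correlation are the "half-agreed" experts and are deliberately excluded.
Each candidate subset is scored by the entropy of its normalized
correlation row divided by its cardinality; the two highest-entropy subsets
are Borda-aggregated into the meta-rankings A1 (headline) and A2 (backup).

The entropy of a subset x anchored at row i is

    E(x) = -(1/|x|) * sum_{j in x} p_j ln p_j,   p_j = m_ij / sum_{k in x} m_ik

so balanced correlation profiles score high and the 1/|x| factor steers the
selection toward smaller subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import WeightedNetwork
from .ranking import Ranking, rank_nodes
from .centrality import compute_rankings

__all__ = [
    "AggregationParams",
    "RankingSet",
    "SubsetCandidate",
    "AggregationResult",
    "correlation_matrix",
    "slice_row",
    "subset_entropy",
    "select_subsets",
    "borda_aggregate",
    "meta_centrality",
]


@dataclass(frozen=True)
class AggregationParams:
    """Slicing thresholds: high-agreement bound t_b, low bound t_s."""

    t_b: float = 0.8
    t_s: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.t_b <= 1:
            raise ValueError("t_b must be in (0, 1]")
        if not 0 <= self.t_s < 1:
            raise ValueError("t_s must be in [0, 1)")
        if self.t_s >= self.t_b:
            raise ValueError("t_s must be smaller than t_b")


class RankingSet:
    """An ordered collection of rankings over a common item set."""

    def __init__(self, rankings: Sequence[Ranking]) -> None:
        if len(rankings) < 2:
            raise ValueError("need at least 2 rankings to aggregate")
        items = rankings[0].nodes
        if len(items) < 2:
            raise ValueError("rankings must cover at least 2 items")
        for r in rankings[1:]:
            if r.nodes != items:
                diff = sorted(items ^ r.nodes)
                raise ValueError(
                    f"rankings cover different item sets; symmetric difference: {diff}"
                )
        self.rankings: tuple[Ranking, ...] = tuple(rankings)
        self.items: tuple[str, ...] = tuple(sorted(items))

    def __len__(self) -> int:
        return len(self.rankings)

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(r.source for r in self.rankings)

    def position_matrix(self) -> np.ndarray:
        """Rankings-by-items matrix of tie-averaged positions."""
        return np.array(
            [[r.positions[it] for it in self.items] for r in self.rankings]
        )


@dataclass(frozen=True)
class SubsetCandidate:
    """A row-anchored candidate subset of ranking indices (0-based)."""

    anchor_row: int
    members: frozenset[int]
    category: str  # "H", "L" or "HL"
    entropy: float = float("nan")

    def with_entropy(self, value: float) -> "SubsetCandidate":
        return SubsetCandidate(self.anchor_row, self.members, self.category, value)


@dataclass(frozen=True)
class AggregationResult:
    """The two meta-rankings and the subsets that produced them."""

    a1: Ranking
    a2: Ranking
    best: SubsetCandidate
    second: SubsetCandidate
    sources: tuple[str, ...]
    correlations: np.ndarray

    @property
    def best_measures(self) -> tuple[str, ...]:
        return tuple(self.sources[i] for i in sorted(self.best.members))

    @property
    def second_measures(self) -> tuple[str, ...]:
        return tuple(self.sources[i] for i in sorted(self.second.members))


def correlation_matrix(ranking_set: RankingSet) -> np.ndarray:
    """Clipped Spearman correlation matrix M in [0, 1]^{n x n}.

    Spearman between two rankings is the Pearson correlation of their
    tie-averaged position vectors. Negative correlations are treated like
    uncorrelated ones and clipped to zero; the diagonal is 1. A ranking with
    all positions tied has no rank variance; its correlations are set to 0.
    """
    pos = ranking_set.position_matrix()
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(pos)
    m = np.nan_to_num(m, nan=0.0)
    m = np.clip(m, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def slice_row(
    m: np.ndarray, i: int, params: AggregationParams
) -> tuple[SubsetCandidate, SubsetCandidate, SubsetCandidate]:
    """High / low / mixed subsets anchored at row *i* (which they contain)."""
    n = m.shape[0]
    high = {j for j in range(n) if j != i and m[i, j] >= params.t_b} | {i}
    low = {j for j in range(n) if j != i and m[i, j] <= params.t_s} | {i}
    return (
        SubsetCandidate(i, frozenset(high), "H"),
        SubsetCandidate(i, frozenset(low), "L"),
        SubsetCandidate(i, frozenset(high | low), "HL"),
    )


def subset_entropy(m: np.ndarray, candidate: SubsetCandidate) -> float:
    """Cardinality-scaled entropy of the normalized correlation row."""
    members = sorted(candidate.members)
    if not members:
        raise ValueError("candidate has no members")
    row = m[candidate.anchor_row, members]
    total = row.sum()
    if total <= 0:
        zeros = [j for j in members if m[candidate.anchor_row, j] == 0]
        raise ValueError(
            f"cannot normalize subset anchored at row {candidate.anchor_row}: all "
            f"correlations are clipped to zero (members {zeros})"
        )
    p = row / total
    ent = float(-(p[p > 0] * np.log(p[p > 0])).sum())
    return ent / len(members)


def enumerate_candidates(
    m: np.ndarray, params: AggregationParams
) -> list[SubsetCandidate]:
    """The full pool: h_i, l_i, hl_i for every row, entropy attached."""
    pool = []
    for i in range(m.shape[0]):
        for cand in slice_row(m, i, params):
            pool.append(cand.with_entropy(subset_entropy(m, cand)))
    return pool


def select_subsets(
    m: np.ndarray, params: AggregationParams
) -> tuple[SubsetCandidate, SubsetCandidate]:
    """Top-two candidates by entropy from the pooled slices of all rows.

    Ties are broken toward smaller cardinality (cheaper aggregations), then
    smaller anchor row, then category order H < HL < L for determinism.
    """
    pool = enumerate_candidates(m, params)
    pool.sort(
        key=lambda c: (-c.entropy, len(c.members), c.anchor_row, c.category)
    )
    best = pool[0]
    second = pool[1] if len(pool) > 1 else best
    return best, second


def borda_aggregate(ranking_set: RankingSet, members: frozenset[int] | set[int]) -> Ranking:
    """Borda count over the member rankings.

    Each item z scores sum_t (|C| - pos_t(z)) over the member rankings t,
    with tie-averaged positions; the descending reorder of the scores is the
    aggregated ranking (standard tie policy).
    """
    if not members:
        raise ValueError("members must be nonempty")
    items = ranking_set.items
    n_items = len(items)
    scores: dict[str, float] = {it: 0.0 for it in items}
    for t in sorted(members):
        r = ranking_set.rankings[t]
        for it in items:
            scores[it] += n_items - r.positions[it]
    return rank_nodes(scores, source="aggregated")


def aggregate_rankings(
    ranking_set: RankingSet, params: AggregationParams | None = None
) -> AggregationResult:
    """Correlate, slice, select, and Borda-aggregate a ranking set."""
    params = params or AggregationParams()
    m = correlation_matrix(ranking_set)
    best, second = select_subsets(m, params)
    a1 = borda_aggregate(ranking_set, best.members)
    a2 = borda_aggregate(ranking_set, second.members)
    return AggregationResult(
        a1=a1,
        a2=a2,
        best=best,
        second=second,
        sources=ranking_set.sources,
        correlations=m,
    )


def meta_centrality(
    network: WeightedNetwork,
    measures: list[str] | None = None,
    params: AggregationParams | None = None,
) -> AggregationResult:
    """End-to-end meta-centrality on a network.

    Computes the requested centrality rankings (all eight by default),
    builds the correlation matrix, selects the two highest-entropy subsets
    and returns their Borda aggregations A1 and A2, with provenance naming
    the measures in each selected subset.
    """
    rankings = compute_rankings(network, measures)
    if len(rankings) < 2:
        raise ValueError("meta-centrality needs at least 2 measures")
    return aggregate_rankings(RankingSet(list(rankings.values())), params)
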