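import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metacentrality import (
    AggregationParams,
    RankingSet,
    SubsetCandidate,
    aggregate_rankings,
    borda_aggregate,
    correlation_matrix,
    make_named_graph,
    meta_centrality,
    rank_nodes,
    select_subsets,
    slice_row,
    subset_entropy,
)
from metacentrality.aggregation import enumerate_candidates

from oracles import naive_borda, naive_select


def ranking_set_from_scores(score_vectors, items=None):
    return RankingSet([rank_nodes(s, source=f"r{i}") for i, s in enumerate(score_vectors)])


def scores_from_order(order):
    """Score vector whose descending ranking equals *order*."""
    n = len(order)
    return {item: float(n - i) for i, item in enumerate(order)}


class TestCorrelationMatrix:
    def test_identical_rankings_fully_correlated(self):
        rs = ranking_set_from_scores([{"a": 3, "b": 2, "c": 1}] * 2)
        assert correlation_matrix(rs)[0, 1] == pytest.approx(1.0)

    def test_reversal_clips_to_zero(self):
        rs = ranking_set_from_scores([{"a": 3, "b": 2, "c": 1}, {"a": 1, "b": 2, "c": 3}])
        assert correlation_matrix(rs)[0, 1] == 0.0

    def test_hand_spearman_four_items(self):
        # positions (1,2,3,4) vs (1,2,4,3): rho = 1 - 6*2/(4*15) = 0.8
        rs = ranking_set_from_scores(
            [scores_from_order("abcd"), scores_from_order("abdc")]
        )
        assert correlation_matrix(rs)[0, 1] == pytest.approx(0.8)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        rs = ranking_set_from_scores(
            [{f"n{i}": float(rng.integers(0, 10)) for i in range(8)} for _ in range(4)]
        )
        m = correlation_matrix(rs)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= 0 and m.max() <= 1

    def test_mismatched_item_sets_rejected(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            RankingSet([rank_nodes({"a": 1, "b": 2}), rank_nodes({"a": 1, "c": 2})])

    def test_all_tied_ranking_treated_as_uncorrelated(self):
        rs = ranking_set_from_scores([{"a": 1, "b": 1, "c": 1}, {"a": 3, "b": 2, "c": 1}])
        m = correlation_matrix(rs)
        assert m[0, 1] == 0.0
        assert m[0, 0] == 1.0


class TestSlicing:
    def fig1_matrix(self):
        """8x8 matrix whose first row has one low correlate (ranking 4),
        three high ones (6, 7, 8) and three in between, under the default
        thresholds t_b=0.8, t_s=0.3."""
        m = np.full((8, 8), 0.5)
        np.fill_diagonal(m, 1.0)
        for j in (5, 6, 7):  # 0-based for rankings 6, 7, 8
            m[0, j] = m[j, 0] = 0.85
        m[0, 3] = m[3, 0] = 0.2  # ranking 4
        return m

    def test_mixed_row_set_structure(self):
        params = AggregationParams(t_b=0.8, t_s=0.3)
        h, l, hl = slice_row(self.fig1_matrix(), 0, params)
        assert h.members == frozenset({0, 5, 6, 7})
        assert l.members == frozenset({0, 3})
        assert hl.members == frozenset({0, 3, 5, 6, 7})

    def test_degenerate_row_keeps_only_anchor(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        h, l, hl = slice_row(m, 1, AggregationParams())
        assert h.members == l.members == hl.members == frozenset({1})

    def test_ts_zero_with_positive_correlations_gives_singleton_low(self):
        m = self.fig1_matrix()
        _, l, _ = slice_row(m, 0, AggregationParams(t_b=0.8, t_s=0.0))
        assert l.members == frozenset({0})


class TestSubsetEntropy:
    def test_singleton_zero(self):
        m = np.eye(3)
        assert subset_entropy(m, SubsetCandidate(0, frozenset({0}), "H")) == 0.0

    def test_pair_with_unit_correlation(self):
        m = np.ones((2, 2))
        e = subset_entropy(m, SubsetCandidate(0, frozenset({0, 1}), "H"))
        assert e == pytest.approx(math.log(2) / 2)

    @pytest.mark.parametrize("size", [2, 3, 5])
    def test_uniform_row_attains_maximum(self, size):
        m = np.ones((size, size))
        uniform = subset_entropy(m, SubsetCandidate(0, frozenset(range(size)), "H"))
        assert uniform == pytest.approx(math.log(size) / size)
        # any non-uniform row over the same members scores lower
        m2 = m.copy()
        m2[0, 1] = 0.3
        assert subset_entropy(m2, SubsetCandidate(0, frozenset(range(size)), "H")) < uniform


class TestSelection:
    def test_two_identical_rankings_prefer_the_pair(self):
        rs = ranking_set_from_scores([{"a": 2, "b": 1}] * 2)
        m = correlation_matrix(rs)
        best, _ = select_subsets(m, AggregationParams())
        assert len(best.members) == 2

    def test_all_singleton_pool_degenerates(self):
        # middling correlations everywhere: every slice is a singleton
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        best, second = select_subsets(m, AggregationParams())
        assert len(best.members) == 1
        assert len(second.members) == 1

    def test_mixed_hl_candidate_can_beat_pure_high(self):
        # With tight thresholds an HL triple whose row is nearly uniform
        # approaches ln(3)/3 ~ 0.366, above the ln(2)/2 ~ 0.347 ceiling of
        # any pure-H pair; rows 1-3 are kept middling so their H slices are
        # weak. Verified against the exhaustive pool oracle.
        m = np.array(
            [
                [1.00, 0.92, 0.85, 0.88],
                [0.92, 1.00, 0.88, 0.88],
                [0.85, 0.88, 1.00, 0.88],
                [0.88, 0.88, 0.88, 1.00],
            ]
        )
        params = AggregationParams(t_b=0.9, t_s=0.85)
        pool = enumerate_candidates(m, params)
        hl0 = next(c for c in pool if c.anchor_row == 0 and c.category == "HL")
        assert hl0.members == frozenset({0, 1, 2})
        pure_h = [c for c in pool if c.category == "H"]
        assert hl0.entropy > max(c.entropy for c in pure_h)
        best, _ = select_subsets(m, params)
        oracle = naive_select(m.tolist(), params.t_b, params.t_s)
        assert best.members == oracle[0][1] == hl0.members

    def test_matches_brute_force_on_seeded_matrices(self):
        params = AggregationParams()
        rng = np.random.default_rng(123)
        for _ in range(100):
            m = rng.uniform(0, 1, size=(8, 8))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            best, second = select_subsets(m, params)
            oracle = naive_select(m.tolist(), params.t_b, params.t_s)
            assert (best.anchor_row, best.members, best.category) == (
                oracle[0][0],
                oracle[0][1],
                oracle[0][2],
            )
            assert (second.anchor_row, second.members, second.category) == (
                oracle[1][0],
                oracle[1][1],
                oracle[1][2],
            )


class TestBorda:
    def test_single_member_is_identity(self):
        rs = ranking_set_from_scores(
            [scores_from_order("cab"), scores_from_order("abc")]
        )
        assert borda_aggregate(rs, {0}).order == ("c", "a", "b")

    def test_hand_example(self):
        rs = ranking_set_from_scores(
            [scores_from_order("abcd"), scores_from_order("badc"), scores_from_order("acbd")]
        )
        agg = borda_aggregate(rs, {0, 1, 2})
        assert agg.scores == {"a": 8.0, "b": 6.0, "c": 3.0, "d": 1.0}
        assert agg.order == ("a", "b", "c", "d")

    def test_idempotent_on_identical_rankings(self):
        rs = ranking_set_from_scores([scores_from_order("dcba")] * 3)
        assert borda_aggregate(rs, {0, 1, 2}).order == ("d", "c", "b", "a")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 3), min_size=4, max_size=4),
            min_size=2,
            max_size=4,
        )
    )
    def test_matches_naive_oracle_with_ties(self, raw):
        items = ["a", "b", "c", "d"]
        score_vectors = [dict(zip(items, map(float, row))) for row in raw]
        rs = ranking_set_from_scores(score_vectors)
        agg = borda_aggregate(rs, set(range(len(score_vectors))))
        want = naive_borda(score_vectors)
        for z in items:
            assert agg.scores[z] == pytest.approx(want[z])

    def test_unanimity_first_place(self):
        # every ranking puts 'z' first -> aggregation puts 'z' first
        rng = np.random.default_rng(7)
        vectors = []
        for _ in range(4):
            scores = {f"n{i}": float(rng.uniform(0, 1)) for i in range(6)}
            scores["z"] = 2.0
            vectors.append(scores)
        rs = ranking_set_from_scores(vectors)
        result = aggregate_rankings(rs)
        assert result.a1.order[0] == "z"

    def test_neutrality_under_relabeling(self):
        vectors = [scores_from_order("abcd"), scores_from_order("badc")]
        relabel = {"a": "w", "b": "x", "c": "y", "d": "z"}
        vectors_relabeled = [
            {relabel[k]: v for k, v in s.items()} for s in vectors
        ]
        out = borda_aggregate(ranking_set_from_scores(vectors), {0, 1})
        out2 = borda_aggregate(ranking_set_from_scores(vectors_relabeled), {0, 1})
        assert tuple(relabel[n] for n in out.order) == out2.order


class TestMetaCentrality:
    def test_duplicated_measure_reduces_to_itself(self, star5):
        result = meta_centrality(star5, measures=["C_D", "C_S"])
        # on a unit-weight star degree and strength coincide
        assert result.a1.order == rank_nodes(
            {n: float(len(star5.neighbors(n))) for n in star5.nodes}
        ).order

    def test_star_unanimously_ranks_hub_first(self, star5):
        result = meta_centrality(star5)
        assert result.a1.order[0] == "v00"
        assert result.a2.order[0] == "v00"

    def test_provenance_uses_measure_tags(self, star5):
        result = meta_centrality(star5)
        valid = {"C_D", "C_S", "C_C", "C_E", "C_P", "C_K", "C_KW", "C_EX"}
        assert set(result.best_measures) <= valid
        assert set(result.second_measures) <= valid
        assert len(result.best_measures) >= 1


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [{"t_b": 0.0}, {"t_b": 1.5}, {"t_s": -0.1}, {"t_s": 1.0},
                   {"t_b": 0.3, "t_s": 0.5}]
    )
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AggregationParams(**kwargs)
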