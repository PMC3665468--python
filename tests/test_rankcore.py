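import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefrank.rankcore import (RankingTable, all_rankings, destat,
                               impute_partial, ordering_to_ranking, rank_agg,
                               ranking_to_ordering)


class TestRankAgg:
    def test_counts_identical_rows(self):
        t = rank_agg([(1, 2, 3), (1, 2, 3), (2, 1, 3)])
        assert t.n == 3
        assert t.n_distinct == 2
        lookup = {tuple(r): f for r, f in zip(t.rankings.astype(int), t.freq)}
        assert lookup == {(1, 2, 3): 2, (2, 1, 3): 1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no rankings"):
            rank_agg(np.empty((0, 3)))

    def test_all_distinct_permutations(self):
        t = rank_agg(all_rankings(3))
        assert t.n_distinct == 6 and t.n == 6
        assert np.all(t.freq == 1)

    def test_rows_sorted_lexicographically(self, rng):
        rows = np.stack([rng.permutation(4) + 1 for _ in range(30)])
        t = rank_agg(rows)
        as_tuples = [tuple(r) for r in t.rankings]
        assert as_tuples == sorted(as_tuples)

    def test_non_permutation_rejected_unless_flagged(self):
        with pytest.raises(ValueError, match="not a permutation"):
            rank_agg([(1, 1, 3)])
        # tie-imputed row sums to k(k+1)/2 and passes with the flag
        t = rank_agg([(1.0, 2.5, 2.5)], allow_ties=True)
        assert t.n == 1

    @given(st.integers(2, 5), st.integers(1, 40), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_aggregation_conserves_count(self, k, n, seed):
        rng = np.random.default_rng(seed)
        rows = np.stack([rng.permutation(k) + 1 for _ in range(n)])
        t = rank_agg(rows)
        assert t.n == n
        # expanding reproduces the multiset of rows
        assert sorted(map(tuple, t.expand())) == sorted(map(tuple, rows))


class TestOrderingConversion:
    def test_direct_inversion(self):
        assert ranking_to_ordering([2, 3, 1]).tolist() == [3, 1, 2]

    def test_identity(self):
        assert ranking_to_ordering([1, 2, 3, 4]).tolist() == [1, 2, 3, 4]

    def test_round_trip_all_k4(self):
        for perm in all_rankings(4):
            assert np.array_equal(
                ranking_to_ordering(ordering_to_ranking(perm)), perm)

    def test_ties_rejected(self):
        with pytest.raises(ValueError, match="ties"):
            ranking_to_ordering([1.0, 2.5, 2.5])


class TestImputePartial:
    @pytest.mark.parametrize("partial, expected", [
        ([1, 2, 3, 4, 5, None, None], [1, 2, 3, 4, 5, 6.5, 6.5]),
        ([1, None, None], [1, 2.5, 2.5]),
        ([2, None, 1], [2, 3.0, 1]),
    ])
    def test_mean_rank_imputation(self, partial, expected):
        out = impute_partial(partial)
        assert np.allclose(out, expected)
        k = len(partial)
        assert np.isclose(out.sum(), k * (k + 1) / 2)

    def test_complete_input_unchanged(self):
        assert impute_partial([3, 1, 2]).tolist() == [3, 1, 2]

    def test_non_prefix_ranks_rejected(self):
        with pytest.raises(ValueError, match="prefix"):
            impute_partial([1, 3, None])


class TestDestat:
    def test_single_ranking(self):
        t = RankingTable(np.array([[1, 2, 3]]), np.array([2]))
        d = destat(t)
        assert np.allclose(d.mean_rank, [1, 2, 3])
        assert d.pair[1, 0] == 2 and d.pair[0, 1] == 0
        assert np.allclose(d.marginal, 2 * np.eye(3))

    def test_full_permutation_set(self):
        t = rank_agg(all_rankings(3))
        d = destat(t)
        assert np.allclose(d.mean_rank, 2.0)
        off = ~np.eye(3, dtype=bool)
        assert np.all(d.pair[off] == 3)
        assert np.all(d.marginal == 2)

    def test_uniform_expectation_k7(self, rng):
        # under uniform sampling each mean rank converges to (k+1)/2 = 4
        rows = np.stack([rng.permutation(7) + 1 for _ in range(4000)])
        d = destat(rank_agg(rows))
        assert np.allclose(d.mean_rank, 4.0, atol=0.15)

    def test_pair_antisymmetry_and_marginal_margins(self, table_factory):
        t = table_factory(k=5, n=80)
        d = destat(t)
        assert np.allclose(d.pair + d.pair.T, t.n * (1 - np.eye(5)))
        assert np.allclose(d.pair.diagonal(), 0)
        assert np.allclose(d.marginal.sum(axis=0), t.n)
        assert np.allclose(d.marginal.sum(axis=1), t.n)

    def test_aggregated_equals_expanded(self, table_factory):
        t = table_factory(k=4, n=60)
        d_agg = destat(t)
        d_ind = destat(rank_agg(t.expand()))
        assert np.allclose(d_agg.mean_rank, d_ind.mean_rank)
        assert np.allclose(d_agg.pair, d_ind.pair)
        assert np.allclose(d_agg.marginal, d_ind.marginal)

    def test_direction_option_transposes_pairs(self, table_factory):
        t = table_factory()
        assert np.allclose(destat(t, direction="preferred").pair,
                           destat(t, direction="greater").pair.T)

    def test_relabeling_permutes_descriptives(self, rng, table_factory):
        t = table_factory(k=4, n=40)
        gamma = rng.permutation(4)              # new item g[i] <- old item i
        relabeled = t.rankings[:, np.argsort(gamma)]
        t2 = RankingTable(relabeled, t.freq.copy())
        d1, d2 = destat(t), destat(t2)
        assert np.allclose(d2.mean_rank, d1.mean_rank[np.argsort(gamma)])
        assert np.allclose(d2.pair, d1.pair[np.ix_(np.argsort(gamma), np.argsort(gamma))])
        assert np.allclose(d2.marginal, d1.marginal[np.argsort(gamma)])

    def test_tied_table_mean_rank_only(self):
        t = RankingTable(np.array([[1.0, 2.5, 2.5]]), np.array([4]), allow_ties=True)
        with pytest.warns(UserWarning, match="mean rank only"):
            d = destat(t)
        assert d.pair is None and d.marginal is None
        assert np.allclose(d.mean_rank, [1, 2.5, 2.5])
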