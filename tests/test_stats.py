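"""Statistical primitives against exhaustive-enumeration oracles."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senprof.stats import (
    bh_adjust,
    fisher_exact_2x2,
    fishers_product,
    hypergeom_enrichment,
    hypergeom_tail,
    mhg_pvalue,
    mhg_statistic,
)


def brute_tail(k, K, n, N):
    """P(X >= k) by enumerating every size-n draw from the universe."""
    hits = total = 0
    universe = list(range(N))
    marked = set(range(K))
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomTail:
    def test_known_value(self):
        # 70 of the 210 size-4 draws from a 10-universe hit >= 2 of 3 marks
        assert hypergeom_tail(2, 3, 4, 10) == pytest.approx(70 / 210, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 3, 4, 10) == 1.0

    def test_impossible_overlap_is_zero(self):
        assert hypergeom_tail(4, 3, 4, 10) == 0.0

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            hypergeom_tail(-1, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 11, 4, 10)

    @pytest.mark.parametrize("N", [5, 8, 10])
    def test_matches_enumeration(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_tail(k, K, n, N) == pytest.approx(
                        brute_tail(k, K, n, N), abs=1e-12
                    )

    def test_monotone_nonincreasing_in_k(self):
        tails = [hypergeom_tail(k, 6, 7, 20) for k in range(7)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestFisherExact:
    def test_one_sided_equals_hypergeom_tail(self):
        # [[k, K-k], [n-k, N-K-n+k]] with k=3, K=5, n=6, N=15
        p = fisher_exact_2x2([[3, 2], [3, 7]], alternative="greater")
        assert p == pytest.approx(hypergeom_tail(3, 5, 6, 15), rel=1e-10)

    def test_bad_shape_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestBHAdjust:
    def test_hand_stepup(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20)
    )
    def test_never_decreases_and_idempotent(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.allclose(bh_adjust(adj), bh_adjust(adj))


class TestMHGStatistic:
    def test_enriched_prefix(self):
        res = mhg_statistic([1, 1, 0, 1, 0, 0])
        assert res.statistic == pytest.approx(0.2, rel=1e-9)
        assert res.threshold == 2  # tie with n'=4 broken to the smaller prefix
        assert res.b_at_threshold == 2

    def test_depleted_prefix_gives_one(self):
        res = mhg_statistic([0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(1.0)

    def test_reversal_increases_statistic(self):
        fwd = mhg_statistic([1, 1, 1, 0, 0, 0, 0]).statistic
        rev = mhg_statistic([0, 0, 0, 0, 1, 1, 1]).statistic
        assert rev > fwd

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            mhg_statistic([1, 1, 1])
        with pytest.raises(ValueError):
            mhg_statistic([0, 0])

    def test_matches_prefix_enumeration(self):
        labels = [1, 0, 1, 1, 0, 0, 1, 0]
        N, B = len(labels), sum(labels)
        prefix = np.cumsum(labels)
        expected = min(
            hypergeom_tail(int(prefix[n - 1]), B, n, N) for n in range(1, N)
        )
        assert mhg_statistic(labels).statistic == pytest.approx(expected)


def brute_mhg_pvalue(mhg, N, B):
    """P(min-HG <= mhg) over every ordering of B ones among N slots."""
    hits = total = 0
    for ones in itertools.combinations(range(N), B):
        total += 1
        labels = [1 if i in ones else 0 for i in range(N)]
        if mhg_statistic(labels).statistic <= mhg * (1 + 1e-9):
            hits += 1
    return hits / total


class TestMHGPvalue:
    @pytest.mark.parametrize("N,B", [(6, 3), (7, 2), (8, 4), (9, 3)])
    def test_matches_full_enumeration(self, N, B):
        for labels in ([1] * B + [0] * (N - B), [0] * (N - B) + [1] * B):
            stat = mhg_statistic(labels).statistic
            assert mhg_pvalue(stat, N, B) == pytest.approx(
                brute_mhg_pvalue(stat, N, B), abs=1e-12
            )

    def test_random_orderings_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            labels = rng.permutation([1] * 3 + [0] * 5)
            stat = mhg_statistic(labels).statistic
            assert mhg_pvalue(stat, 8, 3) == pytest.approx(
                brute_mhg_pvalue(stat, 8, 3), abs=1e-12
            )

    def test_trivial_statistic(self):
        assert mhg_pvalue(1.0, 10, 4) == 1.0

    def test_union_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            labels = rng.permutation([1] * 4 + [0] * 16)
            res = mhg_statistic(labels)
            p = mhg_pvalue(res.statistic, 20, 4)
            assert res.statistic <= p <= min(1.0, 20 * res.statistic) + 1e-12


class TestFishersProduct:
    def test_ones_combine_to_one(self):
        assert fishers_product(1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form(self):
        # for two p-values the chi2_4 tail has the closed form q(1 - ln q)
        for p1, p2 in [(0.05, 0.05), (0.3, 0.01), (0.9, 0.2)]:
            q = p1 * p2
            assert fishers_product(p1, p2) == pytest.approx(
                q * (1 - math.log(q)), rel=1e-10
            )

    def test_symmetric(self):
        assert fishers_product(0.02, 0.7) == fishers_product(0.7, 0.02)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            p = fishers_product(0.0, 0.5)
        assert 0 <= p < 0.5


class TestHypergeomEnrichment:
    def test_single_set_matches_tail(self):
        universe = {f"g{i}" for i in range(10)}
        sets = {"S": {"g0", "g1", "g2"}}
        res = hypergeom_enrichment({"g0", "g1", "g5", "g6"}, sets, universe)
        assert res.loc[0, "p"] == pytest.approx(hypergeom_tail(2, 3, 4, 10))

    def test_disjoint_set_skipped_with_warning(self):
        universe = {"g0", "g1"}
        with pytest.warns(RuntimeWarning):
            res = hypergeom_enrichment({"g0"}, {"S": {"x"}}, universe)
        assert len(res) == 0
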