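import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosie.rankprod import (
    bh_qvalues,
    call_influential,
    consensus_from_scores,
    rank_product,
    rank_with_ties,
    rp_pvalue,
    storey_qvalues,
)


def brute_force_pvalue(rp, n, k):
    """Exhaustive enumeration oracle over all n^k rank tuples."""
    count = sum(
        1
        for tup in itertools.product(range(1, n + 1), repeat=k)
        if np.prod(tup) <= rp + 1e-9
    )
    return count / n**k


class TestRankWithTies:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([5, 3, 3, 1], [1, 2.5, 2.5, 4]),
            ([2, 2, 2, 2], [2.5, 2.5, 2.5, 2.5]),
            ([0.1, 0.9, 0.5], [3, 1, 2]),
        ],
    )
    def test_examples(self, scores, expected):
        np.testing.assert_array_equal(rank_with_ties(scores), expected)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_sum_invariant(self, scores):
        """Ranks (with averaged ties) always sum to n(n+1)/2."""
        r = rank_with_ties(np.array(scores))
        n = len(scores)
        assert abs(r.sum() - n * (n + 1) / 2) < 1e-9


class TestRankProduct:
    def test_elementwise_product(self):
        np.testing.assert_array_equal(
            rank_product([[61, 2, 1], [1, 90, 1], [43, 8, 1]]),
            [2623, 1440, 1],
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            rank_product([[1, 2], [1, 2, 3]])

    def test_needs_two_rankings(self):
        with pytest.raises(ValueError, match="two"):
            rank_product([[1, 2]])


class TestRpPvalue:
    def test_whole_sample_space(self):
        assert rp_pvalue(5**3, 5, 3) == 1.0

    def test_small_enumeration_example(self):
        # n=3, k=2: products <= 3 are (1,1),(1,2),(2,1),(1,3),(3,1)
        assert rp_pvalue(3, 3, 2) == pytest.approx(5 / 9)

    def test_k1_is_floor_over_n(self):
        for rp in (1, 2.7, 5, 9.99, 10):
            assert rp_pvalue(rp, 10, 1) == int(rp) / 10

    @pytest.mark.parametrize("n", [2, 3, 7, 12, 25])
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_enumeration(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        rps = {1, n**k, float(n**k)}
        rps.update(rng.integers(1, n**k, size=5).tolist())
        rps.add(2.5)
        for rp in sorted(rps):
            assert rp_pvalue(rp, n, k) == pytest.approx(
                brute_force_pvalue(rp, n, k), abs=1e-12
            )

    def test_monotone_in_rp(self):
        ps = [rp_pvalue(rp, 30, 3) for rp in range(1, 27000, 500)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rp_pvalue(0.5, 10, 2)
        with pytest.raises(ValueError):
            rp_pvalue(101, 10, 2)

    def test_gamma_approximation_tracks_exact(self):
        # close in the bulk; same order of magnitude in the far tail
        bulk = 200**3 // 2
        assert rp_pvalue(bulk, 200, 3, method="gamma") == pytest.approx(
            rp_pvalue(bulk, 200, 3), rel=0.01
        )
        tail_exact = rp_pvalue(5000, 200, 3)
        tail_gamma = rp_pvalue(5000, 200, 3, method="gamma")
        assert 0.5 * tail_exact < tail_gamma < 2 * tail_exact


class TestQValues:
    def test_single_p(self):
        np.testing.assert_allclose(bh_qvalues([0.03]), [0.03])

    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_qvalues([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_all_equal(self):
        np.testing.assert_allclose(bh_qvalues([0.2, 0.2, 0.2]), 0.2)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_q_dominates_p_and_preserves_order(self, ps):
        p = np.asarray(ps)
        q = bh_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_reduces_to_bh_when_pi0_is_one(self):
        p = np.array([0.6, 0.7, 0.8, 0.9])
        np.testing.assert_allclose(storey_qvalues(p), bh_qvalues(p))


class TestCallInfluential:
    def test_threshold_extremes(self):
        q = [0.01, 0.2, 0.04]
        ids = ["a", "b", "c"]
        assert call_influential(q, ids, q_threshold=0) == []
        assert set(call_influential(q, ids, q_threshold=1.1)) == {"a", "b", "c"}

    def test_sorted_by_q_then_rp(self):
        q = [0.04, 0.01, 0.04]
        rp = [50, 10, 20]
        ids = ["a", "b", "c"]
        assert call_influential(q, ids, rp, 0.05) == ["b", "c", "a"]


class TestConsensus:
    def test_identical_rankings_preserve_order(self):
        scores = np.array([9.0, 1.0, 5.0, 3.0])
        res = consensus_from_scores(
            [scores, scores, scores], np.array(["a", "b", "c", "d"])
        )
        np.testing.assert_array_equal(np.argsort(res.rp), np.argsort(-scores))

    def test_null_calibration(self):
        """Under three independent permutation rankings the fraction of
        p < 0.05 stays within 3 Monte-Carlo SEs of 0.05."""
        rng = np.random.default_rng(12345)
        n, k, reps = 50, 3, 200
        hits = 0
        for _ in range(reps):
            ranks = [rng.permutation(n) + 1 for _ in range(k)]
            rp = rank_product(ranks)
            hits += sum(rp_pvalue(v, n, k) < 0.05 for v in rp)
        frac = hits / (n * reps)
        se = np.sqrt(0.05 * 0.95 / (n * reps))
        assert abs(frac - 0.05) < 3 * se
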