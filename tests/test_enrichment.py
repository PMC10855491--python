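"""Hypergeometric, rank-sum, descriptive summary and BH machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4enrich.annotations import GeneRecord, GenomicInterval
from g4enrich.enrichment import (
    RegionOQSummary,
    count_comparison,
    hypergeom_upper_tail,
    length_comparison,
    ora_with_bh,
    presence_enrichment,
    rank_sum_test,
    summarize_oq_content,
)
from g4enrich.oq_catalog import RegionAssignment


def hypergeom_enumeration(N, K, n, k):
    """Oracle: exact upper tail by enumerating all C(N, n) draws."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / total


def ranksum_enumeration(x, y, alternative="two_sided"):
    """Oracle: exact p over all C(n1+n2, n1) assignments of pooled values
    (tie-free inputs only)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    w_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    ws = [
        sum(ranks[pooled[i]] for i in comb) - n1 * (n1 + 1) / 2
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    total = len(ws)
    if alternative == "greater":
        return sum(w >= w_obs for w in ws) / total
    if alternative == "less":
        return sum(w <= w_obs for w in ws) / total
    mean = n1 * len(y) / 2
    dev = abs(w_obs - mean)
    return min(1.0, sum(abs(w - mean) >= dev for w in ws) / total)


def assignments(counts, region_class="promoter"):
    return [RegionAssignment(f"g{i}", region_class, c) for i, c in enumerate(counts)]


def groups_for(counts, members):
    return {label: {f"g{i}" for i in ids} for label, ids in members.items()}


class TestHypergeom:
    def test_whole_support_gives_one(self):
        assert hypergeom_upper_tail(10, 5, 4, 0).p == pytest.approx(1.0)

    def test_all_successes_matches_closed_form(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_upper_tail(10, 5, 4, 4).p == pytest.approx(5 / 210, rel=1e-12)

    def test_bound_violations_raise(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 11, 4, 0)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 4, 5)  # k > min(n, K)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 9, 8, 6)  # k < n + K - N

    def test_extreme_tail_keeps_exact_log10(self):
        res = hypergeom_upper_tail(48_149, 27_091, 7410, 6779)
        assert res.p > 0
        # reported as 1.72e-1131, far below double-precision underflow
        assert res.log10_p == pytest.approx(math.log10(1.72) - 1131, abs=0.01)

    @pytest.mark.parametrize(
        ("N", "K", "n", "k", "printed"),
        [
            (48_149, 11_358, 7410, 2682, 2.71e-157),
            (48_149, 11_358, 1130, 433, 3.63e-29),
        ],
    )
    def test_genome_scale_parameterizations_match_reported_values(
        self, N, K, n, k, printed
    ):
        res = hypergeom_upper_tail(N, K, n, k)
        assert res.log10_p == pytest.approx(math.log10(printed), abs=0.01)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_agrees_with_enumeration_oracle(self, data):
        N = data.draw(st.integers(2, 9))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        assert hypergeom_upper_tail(N, K, n, k).p == pytest.approx(
            hypergeom_enumeration(N, K, n, k), rel=1e-12
        )


class TestRankSum:
    def test_extreme_low_w_two_sided(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.W == 0 and res.method == "exact"
        assert res.p == pytest.approx(2 / 6)

    def test_central_w_has_p_one(self):
        res = rank_sum_test([1, 4], [2, 3])
        assert res.W == 2 and res.p == pytest.approx(1.0)

    def test_identical_samples_give_p_near_one(self):
        res = rank_sum_test([1, 2, 3] * 10, [1, 2, 3] * 10)
        assert res.ties_present and res.method == "normal_approx"
        assert res.p > 0.95

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_w_bounds_and_one_sided_consistency(self):
        res_g = rank_sum_test([5, 6, 7], [1, 2, 3], alternative="greater")
        assert res_g.W == 9  # n1*n2: complete separation
        assert res_g.p == pytest.approx(1 / 20)  # 1 of C(6,3) arrangements

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_exact_method_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, 11.0))  # tie-free
        n1 = int(rng.integers(2, 8))
        x, y = list(pooled[:n1]), list(pooled[n1:])
        for alternative in ("two_sided", "greater", "less"):
            res = rank_sum_test(x, y, alternative=alternative)
            assert res.method == "exact"
            oracle = ranksum_enumeration(x, y, alternative)
            assert res.p == pytest.approx(oracle, abs=1e-9)


class TestSummaries:
    def test_hand_computed_group_summary(self):
        asn = assignments([0, 2, 1, 0])
        groups = groups_for([0, 2, 1, 0], {"grp": [0, 1, 2, 3]})
        (s,) = summarize_oq_content(asn, groups, "promoter")
        assert (s.n_regions, s.n_with_oq, s.total_oqs_in_oq_regions) == (4, 2, 3)
        assert s.pct_with_oq == 50.0 and s.mean_oq_per_oq_region == 1.50

    def test_unknown_region_id_is_error_listing_it(self):
        asn = assignments([1, 0])
        with pytest.raises(KeyError, match="gZ"):
            summarize_oq_content(asn, {"grp": {"g0", "gZ"}}, "promoter")

    def test_empty_group_mean_is_nan(self):
        (s,) = summarize_oq_content(assignments([0, 0]),
                                    {"grp": {"g0", "g1"}}, "promoter")
        assert s.n_with_oq == 0 and math.isnan(s.mean_exact)

    @pytest.mark.parametrize(
        ("n_with", "n_regions", "total", "pct", "mean"),
        [
            (11_358, 48_149, 17_565, 23.6, 1.55),   # all promoters
            (2682, 7410, 4420, 36.2, 1.65),          # DE promoters
            (433, 1130, 727, 38.3, 1.68),            # 2FC DE promoters
            (27_091, 48_149, 280_899, 56.3, 10.37),  # all gene bodies
            (6779, 7410, 96_482, 91.5, None),        # DE gene bodies (mean 14.2)
        ],
    )
    def test_reported_scale_counts_reproduce_printed_ratios(
        self, n_with, n_regions, total, pct, mean
    ):
        s = RegionOQSummary("promoter", "x", n_regions, n_with, total)
        assert s.pct_with_oq == pct
        if mean is not None:
            assert s.mean_oq_per_oq_region == mean
        else:
            assert round(s.mean_exact, 1) == 14.2


class TestGroupTests:
    def test_group_equal_to_universe_is_degenerate(self):
        asn = assignments([1, 0, 2, 0])
        groups = {"all": {f"g{i}" for i in range(4)}}
        res = presence_enrichment(asn, groups, "promoter", "all")
        assert res.k == res.K and res.n == res.N
        assert res.p == pytest.approx(1.0)

    def test_count_comparison_restricts_to_oq_containing_regions(self):
        asn = assignments([2, 2, 3, 0, 1, 1, 1, 0])
        groups = groups_for([], {"a": [0, 1, 2, 3], "b": [4, 5, 6, 7]})
        res = count_comparison(asn, groups, "promoter", "a", "b",
                               alternative="greater")
        assert (res.n1, res.n2) == (3, 3)  # zeros dropped

    def test_identical_count_vectors_give_p_near_one(self):
        asn = assignments([1, 2, 3, 1, 2, 3])
        groups = groups_for([], {"a": [0, 1, 2], "b": [3, 4, 5]})
        assert count_comparison(asn, groups, "promoter", "a", "b").p > 0.9

    def test_group_without_oq_regions_is_error(self):
        asn = assignments([0, 0, 1])
        groups = groups_for([], {"a": [0, 1], "b": [2]})
        with pytest.raises(ValueError, match="no OQ-containing"):
            count_comparison(asn, groups, "promoter", "a", "b")

    def test_length_comparison_one_sided_enumeration(self):
        genes = [
            GeneRecord(f"g{i}", GenomicInterval("chr1", s, s + l, "+"), "non_coding")
            for i, (s, l) in enumerate([(0, 300), (1000, 400), (2000, 100), (3000, 200)])
        ]
        asn = assignments([1, 1, 1, 1], region_class="gene")
        groups = groups_for([], {"a": [0, 1], "b": [2, 3]})
        res, mean_a, mean_b = length_comparison(genes, asn, groups, "a", "b",
                                                alternative="greater")
        assert (mean_a, mean_b) == (350.0, 150.0)
        assert res.p == pytest.approx(1 / 6)

    def test_length_comparison_equal_groups_p_near_one(self):
        genes = [
            GeneRecord(f"g{i}", GenomicInterval("chr1", 1000 * i, 1000 * i + l, "+"),
                       "non_coding")
            for i, l in enumerate([100, 200, 100, 200])
        ]
        asn = assignments([1, 1, 1, 1], region_class="gene")
        groups = groups_for([], {"a": [0, 1], "b": [2, 3]})
        res, _, _ = length_comparison(genes, asn, groups, "a", "b")
        assert res.p > 0.9


class TestORAWithBH:
    UNIVERSE = {f"g{i}" for i in range(20)}

    def test_bh_hand_example(self):
        # three terms engineered to give raw p ordering, checked via formula
        terms = {"t1": {"g0", "g1"}, "t2": {"g2", "g3"}, "t3": {"g4"}}
        query = {"g0", "g1", "g2", "g5"}
        results = ora_with_bh(terms, query, self.UNIVERSE)
        raw = [r.p for _, r, _ in results]
        adj = [a for _, _, a in results]
        m = len(raw)
        expected = []
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, raw[i] * m / (i + 1))
            expected.append(running)
        expected.reverse()
        assert adj == pytest.approx(expected)

    def test_adjusted_never_below_raw_and_monotone(self):
        terms = {f"t{i}": {f"g{i}", f"g{i+1}"} for i in range(6)}
        results = ora_with_bh(terms, {"g0", "g1", "g2"}, self.UNIVERSE)
        raw = [r.p for _, r, _ in results]
        adj = [a for _, _, a in results]
        assert all(a >= p - 1e-12 for a, p in zip(adj, raw))
        assert all(a1 <= a2 + 1e-12 for a1, a2 in zip(adj, adj[1:]))
        assert all(a <= 1.0 for a in adj)

    def test_single_term_adjusted_equals_raw(self):
        results = ora_with_bh({"t": {"g0", "g1"}}, {"g0"}, self.UNIVERSE)
        (_, res, adj) = results[0]
        assert adj == pytest.approx(res.p)

    def test_disjoint_term_has_k_zero_p_one(self):
        (_, res, _) = ora_with_bh({"t": {"g9", "g10"}}, {"g0", "g1"},
                                  self.UNIVERSE)[0]
        assert res.k == 0 and res.p == pytest.approx(1.0)

    def test_empty_query_is_error(self):
        with pytest.raises(ValueError):
            ora_with_bh({"t": {"g0"}}, set(), self.UNIVERSE)
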