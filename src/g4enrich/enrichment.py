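"""Enrichment statistics: hypergeometric presence tests, rank-sum count
comparisons, descriptive OQ-content summaries, and generic
over-representation with Benjamini-Hochberg control.

The presence test asks whether a gene group (e.g. the DE genes) harbors
regions with at least one OQ more often than expected from the genomic
background: with ``N`` regions overall of which ``K`` contain an OQ, and a
group of ``n`` regions of which ``k`` contain one, the upper-tail
hypergeometric probability is

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n).

Per-region OQ *counts* are compared between groups with the Wilcoxon
rank-sum test (the counts are highly skewed); the statistic reported is
W = (rank sum of the first sample) - n1(n1+1)/2, i.e. the Mann-Whitney U of
the first sample, ranging over [0, n1*n2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .annotations import GeneRecord
from .oq_catalog import RegionAssignment

__all__ = [
    "EnrichmentResult",
    "RankSumResult",
    "RegionOQSummary",
    "hypergeom_upper_tail",
    "rank_sum_test",
    "summarize_oq_content",
    "presence_enrichment",
    "count_comparison",
    "length_comparison",
    "ora_with_bh",
]

#: samples at most this large (n1+n2) use the exact permutation null
EXACT_RANKSUM_LIMIT = 20

_TINY = 5e-324  # smallest positive subnormal double; p is floored here


@dataclass(frozen=True)
class EnrichmentResult:
    """Parameters and upper-tail p of one hypergeometric test.

    ``log10_p`` is exact even where ``p`` itself underflows double precision
    (genome-scale tests can reach p ~ 1e-1000).
    """

    test: str
    N: int
    K: int
    n: int
    k: int
    p: float
    log10_p: float

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p out of (0, 1]")


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum outcome (W = first-sample Mann-Whitney U)."""

    W: float
    p: float
    n1: int
    n2: int
    ties_present: bool
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class RegionOQSummary:
    """Descriptive OQ content of one region class x gene group.

    ``pct_with_oq`` and ``mean_oq_per_oq_region`` carry the report rounding
    (1 decimal for percentages; 2 decimals for means); the ``*_exact``
    properties keep full precision for machine consumption.
    """

    region_class: str
    group: str
    n_regions: int
    n_with_oq: int
    total_oqs_in_oq_regions: int

    def __post_init__(self) -> None:
        if self.n_with_oq > self.n_regions:
            raise ValueError("n_with_oq exceeds n_regions")

    @property
    def pct_exact(self) -> float:
        return 100.0 * self.n_with_oq / self.n_regions if self.n_regions else math.nan

    @property
    def mean_exact(self) -> float:
        if self.n_with_oq == 0:
            return math.nan
        return self.total_oqs_in_oq_regions / self.n_with_oq

    @property
    def pct_with_oq(self) -> float:
        return round(self.pct_exact, 1)

    @property
    def mean_oq_per_oq_region(self) -> float:
        return round(self.mean_exact, 2)

    def as_dict(self) -> dict:
        return {
            "region_class": self.region_class,
            "group": self.group,
            "n_regions": self.n_regions,
            "n_with_oq": self.n_with_oq,
            "total_oqs_in_oq_regions": self.total_oqs_in_oq_regions,
            "pct_with_oq": self.pct_with_oq,
            "mean_oq_per_oq_region": self.mean_oq_per_oq_region,
            "pct_exact": self.pct_exact,
            "mean_exact": self.mean_exact,
        }


def hypergeom_upper_tail(
    N: int, K: int, n: int, k: int, test: str = "hypergeometric"
) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeom(N, K, n), summed in log space.

    Log-space accumulation of the pmf keeps the tail finite down to
    p ~ 1e-1000 and beyond; ``p`` is floored at the smallest positive double
    with the exact value preserved in ``log10_p``.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"bad universe: N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"k={k} outside support [{max(0, n + K - N)}, {min(n, K)}]")
    support = np.arange(k, min(n, K) + 1)
    log_p = float(logsumexp(stats.hypergeom.logpmf(support, N, K, n)))
    log_p = min(log_p, 0.0)  # guard rounding above 1
    p = math.exp(log_p)
    return EnrichmentResult(
        test=test, N=N, K=K, n=n, k=k, p=max(p, _TINY),
        log10_p=log_p / math.log(10),
    )


_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> RankSumResult:
    """Wilcoxon rank-sum / Mann-Whitney test of two independent samples.

    Tie handling uses midranks.  The null is exact (full permutation
    distribution) for tie-free samples with n1+n2 <= 20; otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (not ties) and (x.size + y.size <= EXACT_RANKSUM_LIMIT)
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=_ALTERNATIVES[alternative],
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        W=float(res.statistic),
        p=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        ties_present=bool(ties),
        method="exact" if exact else "normal_approx",
    )


def _counts_by_id(assignments: Sequence[RegionAssignment]) -> dict[str, int]:
    return {a.region_id: a.oq_count for a in assignments}


def _group_counts(
    counts: Mapping[str, int], group: Iterable[str], label: str
) -> np.ndarray:
    ids = sorted(group)
    unknown = [g for g in ids if g not in counts]
    if unknown:
        raise KeyError(
            f"group {label!r} references regions without assignments: "
            f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}"
        )
    return np.array([counts[g] for g in ids], dtype=np.int64)


def summarize_oq_content(
    assignments: Sequence[RegionAssignment],
    groups: Mapping[str, set[str]],
    region_class: str,
) -> list[RegionOQSummary]:
    """One descriptive summary per gene group for the given region class."""
    counts = _counts_by_id(assignments)
    out = []
    for label in groups:
        vec = _group_counts(counts, groups[label], label)
        out.append(
            RegionOQSummary(
                region_class=region_class,
                group=label,
                n_regions=int(vec.size),
                n_with_oq=int(np.count_nonzero(vec)),
                total_oqs_in_oq_regions=int(vec.sum()),
            )
        )
    return out


def presence_enrichment(
    assignments: Sequence[RegionAssignment],
    groups: Mapping[str, set[str]],
    region_class: str,
    group: str,
) -> EnrichmentResult:
    """Hypergeometric presence test: group vs full region universe.

    N = all regions of the class (every assignment row), K = those with at
    least one OQ, n = group size, k = group regions with at least one OQ.
    """
    counts = _counts_by_id(assignments)
    universe = np.array(list(counts.values()), dtype=np.int64)
    vec = _group_counts(counts, groups[group], group)
    return hypergeom_upper_tail(
        N=int(universe.size),
        K=int(np.count_nonzero(universe)),
        n=int(vec.size),
        k=int(np.count_nonzero(vec)),
        test=f"presence:{region_class}:{group}",
    )


def count_comparison(
    assignments: Sequence[RegionAssignment],
    groups: Mapping[str, set[str]],
    region_class: str,
    group_a: str,
    group_b: str,
    alternative: str = "two_sided",
    include_zeros: bool = False,
) -> RankSumResult:
    """Rank-sum comparison of per-region OQ counts between two groups.

    By default restricted to OQ-containing regions in each group (the group
    means are per OQ-containing region); ``include_zeros`` lifts that.
    """
    counts = _counts_by_id(assignments)
    a = _group_counts(counts, groups[group_a], group_a)
    b = _group_counts(counts, groups[group_b], group_b)
    if not include_zeros:
        a, b = a[a > 0], b[b > 0]
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"no OQ-containing {region_class} regions in "
            f"{group_a if a.size == 0 else group_b!r}"
        )
    return rank_sum_test(a, b, alternative=alternative)


def length_comparison(
    genes: Sequence[GeneRecord],
    assignments: Sequence[RegionAssignment],
    groups: Mapping[str, set[str]],
    group_a: str,
    group_b: str,
    alternative: str = "two_sided",
) -> tuple[RankSumResult, float, float]:
    """Compare gene lengths between groups among OQ-containing genes.

    Longer genes hold more OQs by chance alone, so a length difference
    between DE and non-DE genes is a confound for the gene-body comparison;
    this makes it visible.  Returns (rank-sum result, mean length of a,
    mean length of b).
    """
    counts = _counts_by_id(assignments)
    lengths = {g.gene_id: g.length for g in genes}
    vecs = []
    for label in (group_a, group_b):
        ids = [g for g in sorted(groups[label]) if counts.get(g, 0) > 0]
        if not ids:
            raise ValueError(f"no OQ-containing genes in group {label!r}")
        vecs.append(np.array([lengths[g] for g in ids], dtype=float))
    a, b = vecs
    return rank_sum_test(a, b, alternative=alternative), float(a.mean()), float(b.mean())


def ora_with_bh(
    term_sets: Mapping[str, set[str]],
    query: set[str],
    universe: set[str],
) -> list[tuple[str, EnrichmentResult, float]]:
    """Over-representation of each term's gene set in a query set, with BH.

    Terms are reconciled to the universe first; the per-term test is the
    upper-tail hypergeometric with N=|universe|, K=|term|, n=|query|,
    k=|query & term|.  Adjusted p-values follow the Benjamini-Hochberg
    step-up rule, capped at 1.  Results are returned sorted by raw p.
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    query = query & universe
    if not query:
        raise ValueError("query disjoint from universe after reconciliation")
    results = []
    for term in sorted(term_sets):
        term_genes = term_sets[term] & universe
        if not term_genes:
            continue
        results.append(
            (
                term,
                hypergeom_upper_tail(
                    N=len(universe),
                    K=len(term_genes),
                    n=len(query),
                    k=len(query & term_genes),
                    test=f"ora:{term}",
                ),
            )
        )
    if not results:
        raise ValueError("no term overlaps the universe")
    from statsmodels.stats.multitest import multipletests

    raw = np.array([r.p for _, r in results])
    adjusted = multipletests(raw, method="fdr_bh")[1]
    order = np.argsort(raw, kind="stable")
    return [(results[i][0], results[i][1], float(adjusted[i])) for i in order]
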