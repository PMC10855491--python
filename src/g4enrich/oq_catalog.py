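"""Observed-quadruplex (OQ) catalog: condition BEDs, consensus, containment.

G4-Seq detects G4 formation genome-wide under a stabilizing condition; the
catalog used downstream is the *consensus* of two conditions (K+ ions and
pyridostatin): only structure calls supported by both are kept.  Consensus
geometry is the coordinate intersection of every overlapping K+/PDS pair,
with overlapping or bookended results merged — conservative and
deterministic.  An alternative mode keeps the whole K+ interval whenever any
PDS overlap exists (``kplus_anchored``), which changes interval widths and
hence counts.

Region assignment is by *strict containment*: an OQ counts for a promoter or
gene body only when it lies entirely within the region.  An OQ contained in
several (overlapping) regions increments each, keeping per-region counts
independent of the rest of the region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotations import GenomicInterval

__all__ = [
    "OQInterval",
    "RegionAssignment",
    "read_oq_bed",
    "write_oq_bed",
    "intersect_conditions",
    "assign_contained",
    "write_assignments",
]

CONDITION_LABELS = {"Kplus", "PDS", "consensus"}


@dataclass(frozen=True)
class OQInterval:
    """One observed quadruplex interval with its source condition."""

    interval: GenomicInterval
    source: str

    def __post_init__(self) -> None:
        if self.source not in CONDITION_LABELS:
            raise ValueError(f"unknown OQ source {self.source!r}")


@dataclass(frozen=True)
class RegionAssignment:
    """Number of OQs strictly contained in one region."""

    region_id: str
    region_class: str  # "promoter" | "gene"
    oq_count: int

    def __post_init__(self) -> None:
        if self.oq_count < 0:
            raise ValueError("oq_count must be non-negative")


def read_oq_bed(path: str | Path, source: str) -> list[OQInterval]:
    """Read a BED3+ file of OQ calls (half-open coordinates).

    Strand is taken from column 6 when present.  Malformed records raise with
    their line number.
    """
    if source not in CONDITION_LABELS:
        raise ValueError(f"unknown OQ source {source!r}")
    out: list[OQInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval {start}-{end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            out.append(OQInterval(GenomicInterval(chrom, start, end, strand), source))
    return out


def write_oq_bed(oqs: Iterable[OQInterval], path: str | Path) -> None:
    """Write OQ intervals as BED3, sorted by (chrom, start)."""
    rows = sorted(
        (oq.interval.chrom, oq.interval.start, oq.interval.end) for oq in oqs
    )
    with open(path, "w") as handle:
        for chrom, start, end in rows:
            handle.write(f"{chrom}\t{start}\t{end}\n")


def _merge_sorted(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended sorted spans."""
    merged: list[tuple[int, int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def intersect_conditions(
    k_set: Sequence[OQInterval],
    pds_set: Sequence[OQInterval],
    mode: str = "intersect",
) -> list[OQInterval]:
    """Form the consensus OQ catalog from the two stabilizer conditions.

    ``intersect``: emit the coordinate intersection of every K+/PDS pair
    sharing >=1 bp on the same chromosome.  ``kplus_anchored``: emit the K+
    interval itself whenever any PDS interval overlaps it.  Either way the
    result is merged (overlapping/bookended spans coalesced) and sorted.
    """
    if mode not in {"intersect", "kplus_anchored"}:
        raise ValueError(f"unknown consensus mode {mode!r}")
    if not k_set or not pds_set:
        raise ValueError("both condition sets must be non-empty")
    k_chroms = {oq.interval.chrom for oq in k_set}
    p_chroms = {oq.interval.chrom for oq in pds_set}
    if not (k_chroms & p_chroms):
        raise ValueError(
            "condition sets share no chromosome names — naming mismatch? "
            f"(K+ has {sorted(k_chroms)[:3]}..., PDS has {sorted(p_chroms)[:3]}...)"
        )

    by_chrom_k: dict[str, list[tuple[int, int]]] = {}
    by_chrom_p: dict[str, list[tuple[int, int]]] = {}
    for oq in k_set:
        by_chrom_k.setdefault(oq.interval.chrom, []).append(
            (oq.interval.start, oq.interval.end)
        )
    for oq in pds_set:
        by_chrom_p.setdefault(oq.interval.chrom, []).append(
            (oq.interval.start, oq.interval.end)
        )

    consensus: list[OQInterval] = []
    for chrom in sorted(by_chrom_k.keys() & by_chrom_p.keys()):
        ks = sorted(by_chrom_k[chrom])
        ps = sorted(by_chrom_p[chrom])
        spans: list[tuple[int, int]] = []
        i = j = 0
        # classic two-pointer sweep over sorted interval lists
        while i < len(ks) and j < len(ps):
            ks_s, ks_e = ks[i]
            ps_s, ps_e = ps[j]
            lo, hi = max(ks_s, ps_s), min(ks_e, ps_e)
            if lo < hi:
                spans.append((ks_s, ks_e) if mode == "kplus_anchored" else (lo, hi))
            if ks_e <= ps_e:
                i += 1
            else:
                j += 1
        for start, end in _merge_sorted(sorted(spans)):
            consensus.append(
                OQInterval(GenomicInterval(chrom, start, end, "."), "consensus")
            )
    return consensus


def assign_contained(
    regions: Sequence[tuple[str, GenomicInterval]],
    oqs: Sequence[OQInterval],
    region_class: str,
    strand_policy: str = "ignore",
) -> list[RegionAssignment]:
    """Count, per region, the OQs lying entirely within it.

    Containment requires ``oq.start >= region.start`` and
    ``oq.end <= region.end`` on the same chromosome.  With
    ``strand_policy="match"`` an OQ additionally must carry the region's
    strand.  Every input region appears exactly once in the output, zero
    counts included.  Regions with duplicate ids are rejected.
    """
    if strand_policy not in {"ignore", "match"}:
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    ids = [rid for rid, _ in regions]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate region ids within class {region_class!r}")

    def key(iv: GenomicInterval) -> tuple:
        return (iv.chrom, iv.strand) if strand_policy == "match" else (iv.chrom,)

    starts_by: dict[tuple, np.ndarray] = {}
    ends_by: dict[tuple, np.ndarray] = {}
    grouped: dict[tuple, list[tuple[int, int]]] = {}
    for oq in oqs:
        grouped.setdefault(key(oq.interval), []).append(
            (oq.interval.start, oq.interval.end)
        )
    for k, pairs in grouped.items():
        pairs.sort()
        arr = np.asarray(pairs, dtype=np.int64)
        starts_by[k], ends_by[k] = arr[:, 0], arr[:, 1]

    out: list[RegionAssignment] = []
    for region_id, iv in regions:
        k = key(iv)
        count = 0
        if k in starts_by:
            starts, ends = starts_by[k], ends_by[k]
            lo = np.searchsorted(starts, iv.start, side="left")
            hi = np.searchsorted(starts, iv.end, side="left")
            if hi > lo:
                count = int(np.count_nonzero(ends[lo:hi] <= iv.end))
        out.append(RegionAssignment(region_id, region_class, count))
    return out


def write_assignments(
    assignments: Iterable[RegionAssignment], path: str | Path
) -> None:
    """Write assignments as TSV (region_id, region_class, oq_count)."""
    with open(path, "w") as handle:
        handle.write("region_id\tregion_class\toq_count\n")
        for a in assignments:
            handle.write(f"{a.region_id}\t{a.region_class}\t{a.oq_count}\n")
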