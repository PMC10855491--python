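"""Differential-expression table ingest and gene stratification.

The input is a DESeq2-shaped results table (gene_id, log2 fold-change, raw p,
BH-adjusted p).  A gene is called differentially expressed (DE) when its
adjusted p-value is below ``alpha`` (default 0.05); rows whose adjusted p is
missing — e.g. removed by DESeq2's independent filtering — are kept as
non-DE rather than dropped, so the analysis universe stays the full
annotation.  DE genes are further tiered by fold change: tier ``k`` means
|log2FC| >= log2(k), boundaries inclusive ("k-fold or greater").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DERecord",
    "GeneGroupPartition",
    "read_de_table",
    "partition_genes",
    "write_partition",
    "tier_count_summary",
]

DEFAULT_TIERS = (2, 5, 10)
DEFAULT_COLUMNS = {
    "gene_id": "gene_id",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
}


@dataclass(frozen=True)
class DERecord:
    """One gene's DE statistics plus derived significance/tier flags."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float | None
    is_de: bool
    direction: str  # "up" | "down" | "none"
    tier_flags: frozenset[int]

    @classmethod
    def from_stats(
        cls,
        gene_id: str,
        log2fc: float,
        pvalue: float,
        padj: float | None,
        alpha: float = 0.05,
        tiers: Sequence[int] = DEFAULT_TIERS,
    ) -> "DERecord":
        is_de = padj is not None and not math.isnan(padj) and padj < alpha
        if is_de and log2fc > 0:
            direction = "up"
        elif is_de and log2fc < 0:
            direction = "down"
        else:
            direction = "none"
        flags = frozenset(
            k for k in tiers if is_de and abs(log2fc) >= math.log2(k)
        )
        return cls(gene_id, float(log2fc), float(pvalue),
                   None if padj is None or math.isnan(padj) else float(padj),
                   is_de, direction, flags)


@dataclass
class GeneGroupPartition:
    """Named gene-id groups used by the enrichment stage.

    ``DE`` and ``nonDE`` partition the universe; ``DE_2FC`` is the DE subset
    at the first fold tier with ``nonDE_2FC`` its complement in the universe;
    ``up``/``down`` split DE by direction.  ``unmatched`` lists DE-table ids
    absent from the annotation universe (excluded from every group).
    """

    groups: dict[str, set[str]]
    universe: set[str]
    unmatched: list[str] = field(default_factory=list)

    def __getitem__(self, label: str) -> set[str]:
        return self.groups[label]


def read_de_table(
    path: str | Path,
    alpha: float = 0.05,
    tiers: Sequence[int] = DEFAULT_TIERS,
    columns: Mapping[str, str] | None = None,
) -> list[DERecord]:
    """Read a DESeq2-shaped TSV into DE records.

    ``columns`` remaps the logical names gene_id/log2fc/pvalue/padj onto the
    file's headers.  Duplicate gene ids and missing columns are errors.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    ids = df[cols["gene_id"]].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene_id(s) {sorted(set(dup))[:5]}")
    records = []
    for gid, lfc, p, padj in zip(
        ids, df[cols["log2fc"]], df[cols["pvalue"]], df[cols["padj"]]
    ):
        records.append(
            DERecord.from_stats(
                gid,
                float(lfc),
                float(p),
                None if pd.isna(padj) else float(padj),
                alpha=alpha,
                tiers=tiers,
            )
        )
    return records


def partition_genes(
    records: Sequence[DERecord],
    universe: Iterable[str],
    first_tier: int = 2,
) -> GeneGroupPartition:
    """Partition the annotation universe into DE-status groups.

    The non-DE background is the set complement of the DE calls within the
    full annotation universe — untested genes included.  DE-table ids not in
    the universe are reported in ``unmatched`` and excluded.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    unmatched = sorted({r.gene_id for r in records} - universe)
    kept = [r for r in records if r.gene_id in universe]
    de = {r.gene_id for r in kept if r.is_de}
    de_fc = {r.gene_id for r in kept if first_tier in r.tier_flags}
    groups = {
        "DE": de,
        "nonDE": universe - de,
        f"DE_{first_tier}FC": de_fc,
        f"nonDE_{first_tier}FC": universe - de_fc,
        "up": {r.gene_id for r in kept if r.direction == "up"},
        "down": {r.gene_id for r in kept if r.direction == "down"},
        "all": set(universe),
    }
    return GeneGroupPartition(groups=groups, universe=universe, unmatched=unmatched)


def write_partition(partition: GeneGroupPartition, path: str | Path) -> None:
    """Write group membership as a two-column TSV (gene_id, group)."""
    with open(path, "w") as handle:
        handle.write("gene_id\tgroup\n")
        for label in sorted(partition.groups):
            if label == "all":
                continue
            for gid in sorted(partition.groups[label]):
                handle.write(f"{gid}\t{label}\n")


def tier_count_summary(
    records: Sequence[DERecord], tiers: Sequence[int] = DEFAULT_TIERS
) -> dict:
    """Per-direction gene counts at each fold-change tier (plus totals)."""
    summary: dict = {
        "n_genes": len(records),
        "n_de": sum(r.is_de for r in records),
        "n_up": sum(r.direction == "up" for r in records),
        "n_down": sum(r.direction == "down" for r in records),
        "tiers": {},
    }
    for k in tiers:
        summary["tiers"][str(k)] = {
            "up": sum(k in r.tier_flags and r.direction == "up" for r in records),
            "down": sum(k in r.tier_flags and r.direction == "down" for r in records),
        }
    return summary


def write_tier_summary(
    records: Sequence[DERecord], path: str | Path, tiers: Sequence[int] = DEFAULT_TIERS
) -> None:
    with open(path, "w") as handle:
        json.dump(tier_count_summary(records, tiers), handle, indent=2, sort_keys=True)
        handle.write("\n")
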