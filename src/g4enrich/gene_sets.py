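"""Tallies of DE genes against user-supplied gene lists.

Gene lists (transcription factors, oncogenes, helicases, ...) are plain
one-id-per-line text files.  Matching is exact on gene_id, optionally after
applying an alias map (two-column TSV: alias, gene_id).  Duplicates in a
list are ignored; list ids that match no DE record are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .de_results import DERecord

__all__ = ["GeneSetTally", "tally_set", "read_gene_list", "read_alias_map"]


@dataclass(frozen=True)
class GeneSetTally:
    """DE membership counts for one gene set, by direction and fold tier."""

    set_name: str
    n_de_in_set: int
    n_up: int
    n_down: int
    n_up_tier2: int
    n_down_tier2: int
    unmatched: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "n_de_in_set": self.n_de_in_set,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_up_tier2": self.n_up_tier2,
            "n_down_tier2": self.n_down_tier2,
            "n_unmatched": len(self.unmatched),
        }


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-id-per-line gene list (blank lines and # comments skipped)."""
    ids = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (alias, gene_id) into a mapping."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[fields[0]] = fields[1]
    return out


def tally_set(
    set_name: str,
    set_genes: Iterable[str],
    records: Sequence[DERecord],
    tier: int = 2,
    alias_map: Mapping[str, str] | None = None,
) -> GeneSetTally:
    """Count DE genes inside a gene set, split by direction and fold tier."""
    ids = {alias_map.get(g, g) if alias_map else g for g in set_genes}
    if not ids:
        raise ValueError(f"gene set {set_name!r} empty after reconciliation")
    by_id = {r.gene_id: r for r in records}
    unmatched = tuple(sorted(ids - by_id.keys()))
    members = [by_id[g] for g in ids if g in by_id]
    de = [r for r in members if r.is_de]
    return GeneSetTally(
        set_name=set_name,
        n_de_in_set=len(de),
        n_up=sum(r.direction == "up" for r in de),
        n_down=sum(r.direction == "down" for r in de),
        n_up_tier2=sum(r.direction == "up" and tier in r.tier_flags for r in de),
        n_down_tier2=sum(r.direction == "down" and tier in r.tier_flags for r in de),
        unmatched=unmatched,
    )
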