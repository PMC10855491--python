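"""Gene annotation ingest and promoter / gene-body interval derivation.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open ``[start, end)``.  GTF/GFF3
input (1-based closed) is converted at the I/O boundary; BED input/output is
already half-open and passes through unchanged.

The promoter of a gene is the fixed-width window directly upstream of its
transcription start site, taken strand-aware from the gene span: for a +
strand gene ``[s, e)`` it is ``[s - w, s)``, for a - strand gene ``[e, e + w)``.
One promoter per gene; windows running off a chromosome end are clipped and
flagged, and genes whose promoter clips to zero length yield no promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "PromoterRegion",
    "read_gene_annotation",
    "derive_promoters",
    "gene_body_intervals",
    "write_bed6",
    "read_bed6",
]

VALID_STRANDS = {"+", "-", "."}

#: attribute keys probed (in order) for the gene biotype in GTF/GFF3 input
BIOTYPE_KEYS = ("gene_biotype", "gene_type", "biotype")

#: required column order of the simple TSV annotation dialect
TSV_COLUMNS = ("gene_id", "chrom", "start", "end", "strand", "biotype")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and other.start >= self.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: span, strand and two-way biotype classification."""

    gene_id: str
    interval: GenomicInterval
    biotype: str  # "protein_coding" | "non_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got "
                f"{self.interval.strand!r}"
            )
        if self.biotype not in {"protein_coding", "non_coding"}:
            raise ValueError(f"gene {self.gene_id}: bad biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def tss(self) -> int:
        """5' end of the gene span (start on +, end on -)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end


@dataclass(frozen=True)
class PromoterRegion:
    """The upstream promoter window of one gene (at most one per gene)."""

    gene_id: str
    interval: GenomicInterval
    window: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if len(self.interval) > self.window:
            raise ValueError(
                f"promoter of {self.gene_id} longer than its window {self.window}"
            )


def _normalize_chrom(chrom: str, strip_chr: bool) -> str:
    if strip_chr and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def _two_way_biotype(raw: str) -> str:
    return "protein_coding" if raw == "protein_coding" else "non_coding"


def _genes_from_gxf(
    path: Path, id_attribute: str | None
) -> Iterable[tuple[str, str, int, int, str, str]]:
    """Yield (gene_id, chrom, start0, end, strand, biotype) from GTF/GFF3.

    gffutils' DataIterator sniffs the dialect and parses attributes; we keep
    only ``gene`` features and convert 1-based closed spans to half-open.
    """
    from gffutils.iterators import DataIterator

    for feature in DataIterator(str(path)):
        if feature.featuretype != "gene":
            continue
        attrs = feature.attributes
        if id_attribute is not None:
            candidates = (id_attribute,)
        else:
            candidates = ("gene_id", "ID")
        gene_id = None
        for key in candidates:
            if key in attrs and attrs[key]:
                gene_id = attrs[key][0]
                break
        if gene_id is None:
            raise ValueError(
                f"{path}: gene feature at {feature.seqid}:{feature.start} "
                f"has no id attribute among {candidates}"
            )
        biotype = "non_coding"
        for key in BIOTYPE_KEYS:
            if key in attrs and attrs[key]:
                biotype = attrs[key][0]
                break
        yield gene_id, feature.seqid, feature.start - 1, feature.end, feature.strand, biotype


def _genes_from_tsv(path: Path) -> Iterable[tuple[str, str, int, int, str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: TSV annotation missing columns {missing}")
    for row in df.itertuples(index=False):
        yield (
            str(row.gene_id),
            str(row.chrom),
            int(row.start),
            int(row.end),
            str(row.strand),
            str(row.biotype),
        )


def read_gene_annotation(
    path: str | Path,
    dialect: str = "gtf",
    chrom_filter: Iterable[str] | None = None,
    strip_chr: bool = False,
    id_attribute: str | None = None,
) -> list[GeneRecord]:
    """Read gene-level records from a GTF, GFF3 or simple-TSV annotation.

    Parameters
    ----------
    dialect
        ``gtf`` / ``gff3`` (parsed with gffutils, 1-based closed converted to
        half-open) or ``tsv`` (columns gene_id, chrom, start, end, strand,
        biotype, already half-open).
    chrom_filter
        If given, only genes on these (post-normalization) chromosome names
        are kept.
    strip_chr
        Drop a leading ``chr`` prefix from chromosome names so mixed-dialect
        resources can be combined.
    id_attribute
        GTF/GFF attribute holding the gene id (default: gene_id, then ID).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect in {"gtf", "gff3"}:
        rows = _genes_from_gxf(path, id_attribute)
    elif dialect == "tsv":
        rows = _genes_from_tsv(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    allowed = set(chrom_filter) if chrom_filter is not None else None
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for gene_id, chrom, start, end, strand, biotype in rows:
        chrom = _normalize_chrom(chrom, strip_chr)
        if allowed is not None and chrom not in allowed:
            continue
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, start, end, strand),
                biotype=_two_way_biotype(biotype),
            )
        )
    if not genes:
        raise ValueError(f"{path}: no gene records left after filtering")
    return genes


def derive_promoters(
    genes: Sequence[GeneRecord],
    chrom_sizes: Mapping[str, int],
    window: int = 1000,
) -> tuple[list[PromoterRegion], list[str]]:
    """Derive one strand-aware upstream promoter per gene.

    Returns ``(promoters, skipped_gene_ids)`` where the second element lists
    genes whose promoter clipped to zero length (TSS at a chromosome edge).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    promoters: list[PromoterRegion] = []
    skipped: list[str] = []
    for gene in genes:
        iv = gene.interval
        if iv.chrom not in chrom_sizes:
            raise KeyError(
                f"gene {gene.gene_id}: chromosome {iv.chrom!r} not in chrom_sizes"
            )
        size = chrom_sizes[iv.chrom]
        if iv.strand == "+":
            start, end = max(0, iv.start - window), iv.start
        else:
            start, end = iv.end, min(size, iv.end + window)
        if start >= end:
            skipped.append(gene.gene_id)
            continue
        promoters.append(
            PromoterRegion(
                gene_id=gene.gene_id,
                interval=GenomicInterval(iv.chrom, start, end, iv.strand),
                window=window,
                clipped=(end - start) < window,
            )
        )
    return promoters, skipped


def gene_body_intervals(
    genes: Sequence[GeneRecord],
) -> list[tuple[str, GenomicInterval]]:
    """Extract each gene's full annotated span, order-stable."""
    return [(gene.gene_id, gene.interval) for gene in genes]


def write_bed6(
    regions: Iterable[tuple[str, GenomicInterval]], path: str | Path
) -> None:
    """Write (name, interval) pairs as BED6 (score 0)."""
    with open(path, "w") as handle:
        for name, iv in regions:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_bed6(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read BED6 back into (name, interval) pairs."""
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            out.append((name, GenomicInterval(chrom, int(start), int(end), strand)))
    return out
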