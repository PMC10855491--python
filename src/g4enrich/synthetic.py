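"""Synthetic annotation / OQ / DE generator with exact planted ground truth.

The generator emulates the statistical structure the enrichment analysis
assumes: a genome of a few chromosomes carrying non-overlapping genes with
log-normal lengths (~1-100 kb) on both strands; observed-quadruplex (OQ)
intervals of 15-50 bp dropped at a baseline density ``lambda0`` per kb, with
a multiplicative enrichment ``rho`` inside the promoters and bodies of a
designated differentially-expressed (DE) gene subset; and a DESeq2-shaped DE
table whose adjusted p-values place exactly that subset below alpha, with
log2 fold-changes spanning the 2-/5-/10-fold tiers.

Exact truth bookkeeping
-----------------------
Every planted OQ must survive the consensus step unchanged and be counted by
strict containment exactly once, in exactly its target region.  Three
geometric rules guarantee that:

* each gene is placed as one block (promoter + body), blocks never overlap,
  so promoter-planted OQs cannot fall inside any gene body and vice versa;
* planted OQs keep a ``margin`` (6 bp) to their region's edges and a ``pad``
  (12 bp) to each other, while the two condition BEDs extend each OQ by at
  most ``ext_max`` (5 bp) — K+ to the left, pyridostatin to the right — so
  pairwise intersections reproduce each OQ exactly and no two consensus
  intervals can touch or merge;
* condition-private decoy intervals (present in one BED only, to exercise
  the consensus step) are placed in intergenic gaps, mutually
  non-overlapping, and therefore never survive the intersection.

Per-region planted counts in ``truth.json`` are the *realized* Poisson
draws, so downstream recovery can demand exact equality.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import GeneRecord, GenomicInterval, PromoterRegion, derive_promoters
from .oq_catalog import OQInterval

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "generate",
           "recover_truth", "RecoveryReport"]

# geometric safety margins; see module docstring
_MARGIN = 6       # bp kept free at each region edge
_PAD = 12         # bp kept free between neighboring planted OQs
_EXT_MAX = 5      # max one-sided condition-specific extension, < _PAD/2


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.  Defaults are the study conditions exercised by
    the statistical property checks (5000 genes, baseline 0.5 OQ/kb, 3-fold
    planted enrichment, 15% DE genes)."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 30_000_000
    n_genes: int = 5000
    gene_len_meanlog: float = math.log(10_000)
    gene_len_sdlog: float = 1.0
    gene_len_min: int = 1_000
    gene_len_max: int = 100_000
    p_plus_strand: float = 0.5
    p_protein_coding: float = 0.46
    promoter_window: int = 1000
    lambda0: float = 0.5          # baseline OQ density, expected OQs per kb
    rho: float = 3.0              # density multiplier in DE promoters/bodies
    oq_len_min: int = 15
    oq_len_max: int = 50
    de_fraction: float = 0.15
    frac_up: float = 0.543        # 4026 of 7410 DE genes upregulated
    # mass of |log2FC| across (<2x, 2-5x, 5-10x, >=10x) for DE genes
    tier_weights: tuple[float, float, float, float] = (0.848, 0.132, 0.0155, 0.0045)
    padj_missing_frac: float = 0.02   # non-DE rows with NA adjusted p
    decoy_lambda: float = 0.1     # condition-private decoys per intergenic kb
    annotation_format: str = "tsv"   # "tsv" | "gtf"

    def __post_init__(self) -> None:
        if self.rho < 0 or self.lambda0 <= 0:
            raise ValueError("require rho >= 0 and lambda0 > 0")
        if not (0 < self.de_fraction < 1):
            raise ValueError("de_fraction must be in (0, 1)")
        if self.annotation_format not in {"tsv", "gtf"}:
            raise ValueError(f"unknown annotation format {self.annotation_format!r}")

    def run_id(self) -> str:
        digest = hashlib.md5(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:10]
        return f"seed{self.seed}-{digest}"


@dataclass
class SyntheticDataset:
    """In-memory generated dataset plus its ground truth."""

    config: SyntheticConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneRecord]
    promoters: list[PromoterRegion]
    k_oqs: list[OQInterval]
    pds_oqs: list[OQInterval]
    de_table: pd.DataFrame
    truth: dict


def _place_in_region(
    rng: np.random.Generator,
    region_start: int,
    region_end: int,
    count: int,
    len_min: int,
    len_max: int,
    margin: int,
    pad: int,
) -> list[tuple[int, int]]:
    """Place up to *count* non-overlapping intervals uniformly in a region.

    Intervals keep *margin* bp to the region edges and >= *pad* bp to each
    other.  If the draw does not fit, the count is truncated to what does.
    """
    usable = region_end - region_start - 2 * margin
    if count <= 0 or usable < len_min + pad:
        return []
    lengths = rng.integers(len_min, len_max + 1, size=count)
    eff = lengths + pad
    total = np.cumsum(eff)
    fit = int(np.searchsorted(total, usable, side="right"))
    if fit < count:
        lengths, eff = lengths[:fit], eff[:fit]
        count = fit
    if count == 0:
        return []
    slack = usable - int(eff.sum())
    u = np.sort(rng.random(count)) * slack
    offsets = np.concatenate([[0], np.cumsum(eff)[:-1]])
    starts = region_start + margin + u.astype(np.int64) + offsets
    return list(zip(starts.tolist(), (starts + lengths).tolist()))


def _place_genes(
    rng: np.random.Generator, config: SyntheticConfig
) -> tuple[list[GeneRecord], list[tuple[str, int, int]]]:
    """Place genes as disjoint promoter+body blocks; return genes and the
    per-chromosome intergenic gaps left over (for decoys)."""
    c = config
    raw = rng.lognormal(c.gene_len_meanlog, c.gene_len_sdlog, size=c.n_genes)
    lengths = np.clip(raw, c.gene_len_min, c.gene_len_max).astype(np.int64)
    strands = np.where(rng.random(c.n_genes) < c.p_plus_strand, "+", "-")
    coding = rng.random(c.n_genes) < c.p_protein_coding

    chrom_of = np.arange(c.n_genes) % c.n_chroms  # round-robin assignment
    genes: list[GeneRecord] = []
    gaps: list[tuple[str, int, int]] = []
    width = len(str(c.n_genes))
    for ci in range(c.n_chroms):
        chrom = f"chr{ci + 1}"
        idx = np.flatnonzero(chrom_of == ci)
        blocks = lengths[idx] + c.promoter_window
        total = int(blocks.sum())
        if total > 0.95 * c.chrom_length:
            raise ValueError(
                f"{chrom}: gene blocks need {total} bp of {c.chrom_length}; "
                "reduce n_genes or gene lengths, or increase chrom_length"
            )
        u = np.sort(rng.random(idx.size)) * (c.chrom_length - total)
        offsets = np.concatenate([[0], np.cumsum(blocks)[:-1]])
        block_starts = u.astype(np.int64) + offsets
        prev_end = 0
        for j, gi in enumerate(idx):
            bs = int(block_starts[j])
            be = bs + int(blocks[j])
            if bs > prev_end:
                gaps.append((chrom, prev_end, bs))
            prev_end = be
            glen = int(lengths[gi])
            if strands[gi] == "+":
                gstart = bs + c.promoter_window  # promoter occupies [bs, gstart)
            else:
                gstart = bs                      # promoter occupies [bs+glen, be)
            genes.append(
                GeneRecord(
                    gene_id=f"g{gi:0{width}d}",
                    interval=GenomicInterval(chrom, gstart, gstart + glen, str(strands[gi])),
                    biotype="protein_coding" if coding[gi] else "non_coding",
                )
            )
        if prev_end < c.chrom_length:
            gaps.append((chrom, prev_end, c.chrom_length))
    genes.sort(key=lambda g: g.gene_id)
    return genes, gaps


def _de_table(
    rng: np.random.Generator, config: SyntheticConfig, gene_ids: Sequence[str],
    de_mask: np.ndarray,
) -> pd.DataFrame:
    c = config
    n = len(gene_ids)
    log2fc = np.empty(n)
    padj = np.empty(n)
    de_idx = np.flatnonzero(de_mask)
    non_idx = np.flatnonzero(~de_mask)
    # |log2FC| bins: below 2-fold, 2-5x, 5-10x, >=10x
    lo = np.array([0.05, 1.0, math.log2(5), math.log2(10)])
    hi = np.array([1.0, math.log2(5), math.log2(10), 4.5])
    weights = np.asarray(c.tier_weights) / sum(c.tier_weights)
    tier = rng.choice(4, size=de_idx.size, p=weights)
    mag = lo[tier] + rng.random(de_idx.size) * (hi[tier] - lo[tier])
    sign = np.where(rng.random(de_idx.size) < c.frac_up, 1.0, -1.0)
    log2fc[de_idx] = sign * mag
    padj[de_idx] = rng.uniform(1e-8, 0.0499, size=de_idx.size)
    log2fc[non_idx] = rng.normal(0.0, 0.2, size=non_idx.size)
    padj[non_idx] = rng.uniform(0.051, 1.0, size=non_idx.size)
    pvalue = padj * rng.uniform(0.1, 1.0, size=n)
    # a realistic slice of non-DE rows loses padj to independent filtering
    non_de = np.flatnonzero(~de_mask)
    n_missing = int(round(c.padj_missing_frac * non_de.size))
    if n_missing:
        drop = rng.choice(non_de, size=n_missing, replace=False)
        padj[drop] = np.nan
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "log2fc": log2fc, "pvalue": pvalue, "padj": padj}
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset in memory (single RNG stream from seed)."""
    c = config
    rng = np.random.default_rng(c.seed)
    genes, gaps = _place_genes(rng, c)
    chrom_sizes = {f"chr{i + 1}": c.chrom_length for i in range(c.n_chroms)}
    promoters, skipped = derive_promoters(genes, chrom_sizes, window=c.promoter_window)
    assert not skipped  # block placement keeps every promoter inside its chrom
    prom_by_gene = {p.gene_id: p for p in promoters}

    n_de = int(round(c.de_fraction * c.n_genes))
    de_idx = rng.choice(c.n_genes, size=n_de, replace=False)
    de_mask = np.zeros(c.n_genes, dtype=bool)
    de_mask[de_idx] = True
    gene_ids = [g.gene_id for g in genes]
    de_genes = sorted(gene_ids[i] for i in np.flatnonzero(de_mask))

    # regions in fixed order (promoter then body, per gene); one Poisson draw
    region_list: list[tuple[str, str, GenomicInterval]] = []
    for i, gene in enumerate(genes):
        region_list.append(("promoter", gene.gene_id, prom_by_gene[gene.gene_id].interval))
        region_list.append(("gene", gene.gene_id, gene.interval))
    mult = np.where(np.repeat(de_mask, 2), c.rho, 1.0)
    lens = np.array([len(iv) for _, _, iv in region_list], dtype=float)
    drawn = rng.poisson(c.lambda0 * mult * lens / 1000.0)

    promoter_counts: dict[str, int] = {}
    gene_counts: dict[str, int] = {}
    placed_all: list[tuple[str, int, int]] = []
    for (region_kind, gene_id, iv), m in zip(region_list, drawn):
        placed = (
            _place_in_region(
                rng, iv.start, iv.end, int(m),
                c.oq_len_min, c.oq_len_max, _MARGIN, _PAD,
            )
            if m else []
        )
        target = promoter_counts if region_kind == "promoter" else gene_counts
        target[gene_id] = len(placed)
        placed_all.extend((iv.chrom, s, e) for s, e in placed)
    n_consensus = len(placed_all)
    # condition-specific one-sided extensions (< half the inter-OQ pad, so
    # pairwise intersection reproduces each planted OQ exactly)
    ext = rng.integers(0, _EXT_MAX + 1, size=(max(n_consensus, 1), 2))
    k_oqs = [
        OQInterval(GenomicInterval(chrom, s - int(a), e, "."), "Kplus")
        for (chrom, s, e), (a, _) in zip(placed_all, ext)
    ]
    pds_oqs = [
        OQInterval(GenomicInterval(chrom, s, e + int(b), "."), "PDS")
        for (chrom, s, e), (_, b) in zip(placed_all, ext)
    ]

    # condition-private decoys in intergenic gaps, mutually non-overlapping
    n_decoys = {"Kplus": 0, "PDS": 0}
    gap_lams = np.array([(e - s) / 1000.0 for _, s, e in gaps]) * c.decoy_lambda
    decoy_k = rng.poisson(gap_lams)
    decoy_p = rng.poisson(gap_lams)
    for (chrom, gstart, gend), n_k, n_p in zip(gaps, decoy_k, decoy_p):
        if n_k + n_p == 0:
            continue
        placed = _place_in_region(
            rng, gstart, gend, int(n_k + n_p), c.oq_len_min, c.oq_len_max, 1, 2
        )
        labels = np.array(["Kplus"] * n_k + ["PDS"] * n_p)[: len(placed)]
        rng.shuffle(labels)
        for (s, e), lab in zip(placed, labels):
            oq = OQInterval(GenomicInterval(chrom, s, e, "."), str(lab))
            (k_oqs if lab == "Kplus" else pds_oqs).append(oq)
            n_decoys[str(lab)] += 1

    de_table = _de_table(rng, c, gene_ids, de_mask)
    de_2fc = sorted(
        de_table.gene_id[(de_mask) & (np.abs(de_table.log2fc) >= 1.0)].tolist()
    )
    truth = {
        "run_id": c.run_id(),
        "seed": c.seed,
        "config": asdict(c),
        "de_genes": de_genes,
        "de_2fc_genes": de_2fc,
        "promoter_counts": promoter_counts,
        "gene_counts": gene_counts,
        "n_consensus_oqs": n_consensus,
        "n_decoys_kplus": n_decoys["Kplus"],
        "n_decoys_pds": n_decoys["PDS"],
    }
    return SyntheticDataset(
        config=c,
        chrom_sizes=chrom_sizes,
        genes=genes,
        promoters=promoters,
        k_oqs=k_oqs,
        pds_oqs=pds_oqs,
        de_table=de_table,
        truth=truth,
    )


def _write_annotation_tsv(dataset: SyntheticDataset, path: Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# seed={dataset.config.seed}\n")
        handle.write("gene_id\tchrom\tstart\tend\tstrand\tbiotype\n")
        for g in dataset.genes:
            iv = g.interval
            handle.write(
                f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{g.biotype}\n"
            )


def _write_annotation_gtf(dataset: SyntheticDataset, path: Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# seed={dataset.config.seed}\n")
        for g in dataset.genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            handle.write(
                f"{iv.chrom}\tg4enrich_sim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def _write_oq_bed(oqs: list[OQInterval], seed: int, path: Path) -> None:
    rows = sorted((o.interval.chrom, o.interval.start, o.interval.end) for o in oqs)
    with open(path, "w") as handle:
        handle.write(f"# seed={seed}\n")
        for chrom, s, e in rows:
            handle.write(f"{chrom}\t{s}\t{e}\n")


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def generate(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the synthetic inputs plus ``truth.json``.

    Returns the paths written.  Output is byte-identical for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = generate_dataset(config)
    paths = {
        "annotation": outdir / (
            "genes.gtf" if config.annotation_format == "gtf" else "genes.tsv"
        ),
        "oq_kplus": outdir / "oq_kplus.bed",
        "oq_pds": outdir / "oq_pds.bed",
        "de_table": outdir / "de_table.tsv",
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "truth": outdir / "truth.json",
    }
    if config.annotation_format == "gtf":
        _write_annotation_gtf(dataset, paths["annotation"])
    else:
        _write_annotation_tsv(dataset, paths["annotation"])
    _write_oq_bed(dataset.k_oqs, config.seed, paths["oq_kplus"])
    _write_oq_bed(dataset.pds_oqs, config.seed, paths["oq_pds"])
    with open(paths["de_table"], "w") as handle:
        handle.write(f"# seed={config.seed}\n")
        dataset.de_table.to_csv(handle, sep="\t", index=False, float_format="%.10g")
    with open(paths["chrom_sizes"], "w") as handle:
        for chrom, size in dataset.chrom_sizes.items():
            handle.write(f"{chrom}\t{size}\n")
    truth = dict(dataset.truth)
    truth["input_md5"] = {
        name: _md5(paths[name])
        for name in ("annotation", "oq_kplus", "oq_pds", "de_table")
    }
    with open(paths["truth"], "w") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return paths


# ---------------------------------------------------------------------------
# truth recovery


@dataclass
class RecoveryReport:
    """Outcome of checking a pipeline report against planted truth."""

    ok: bool
    n_compared: int
    mismatches: list[str] = field(default_factory=list)


def _expected_summary(counts: dict[str, int], group: set[str]) -> tuple[int, int, int]:
    vec = [counts[g] for g in group]
    return len(vec), sum(v > 0 for v in vec), sum(vec)


def recover_truth(
    report: dict | str | Path, truth: dict | str | Path
) -> RecoveryReport:
    """Compare a pipeline report (and its per-region TSVs) to planted truth.

    Counts must match exactly; statistical decisions need only agree in
    direction when an enrichment was actually planted (rho >= 2).  The two
    files must come from the same run, established via input checksums.
    """
    report_path: Path | None = None
    if not isinstance(report, dict):
        report_path = Path(report)
        report = json.loads(report_path.read_text())
    if not isinstance(truth, dict):
        truth = json.loads(Path(truth).read_text())

    truth_md5 = set(truth.get("input_md5", {}).values())
    report_md5 = set(report.get("inputs", {}).values())
    if truth_md5 and not truth_md5 <= report_md5:
        raise ValueError(
            "run mismatch: truth input checksums not among the report's inputs"
        )

    mismatches: list[str] = []
    n = 0
    de = set(truth["de_genes"])
    all_genes = set(truth["gene_counts"])
    groups = {
        "DE": de,
        "nonDE": all_genes - de,
        "DE_2FC": set(truth["de_2fc_genes"]),
        "nonDE_2FC": all_genes - set(truth["de_2fc_genes"]),
        "all": all_genes,
    }
    counts_of = {"promoter": truth["promoter_counts"], "gene": truth["gene_counts"]}
    for region_class, section in report.get("region_classes", {}).items():
        counts = counts_of[region_class]
        for summary in section.get("summaries", []):
            group = groups.get(summary["group"])
            if group is None:
                continue
            n += 1
            expected = _expected_summary(counts, group)
            got = (
                summary["n_regions"],
                summary["n_with_oq"],
                summary["total_oqs_in_oq_regions"],
            )
            if expected != got:
                mismatches.append(
                    f"{region_class}/{summary['group']}: "
                    f"expected (n, n_with_oq, total)={expected}, got {got}"
                )
        rho = truth["config"]["rho"]
        tests = section.get("tests", {})
        # gene bodies are long enough that presence saturates in both groups
        # at small n; only the promoter presence decision is checkable
        if rho >= 2 and region_class == "promoter" and "presence_DE" in tests:
            n += 1
            if tests["presence_DE"]["p"] >= 0.05:
                mismatches.append(
                    f"{region_class}: planted rho={rho} but presence test "
                    f"p={tests['presence_DE']['p']:.3g} not significant"
                )

    # per-region diff when the report points at its assignment TSVs
    files = report.get("files", {})
    base = report_path.parent if report_path else Path(".")
    for region_class, key in (("promoter", "assignments_promoter"),
                              ("gene", "assignments_gene")):
        if key not in files:
            continue
        tsv = base / files[key]
        if not tsv.exists():
            continue
        df = pd.read_csv(tsv, sep="\t")
        observed = dict(zip(df.region_id.astype(str), df.oq_count.astype(int)))
        counts = counts_of[region_class]
        for gid, expected in counts.items():
            n += 1
            got = observed.get(gid)
            if got != expected:
                mismatches.append(
                    f"{region_class}/{gid}: planted {expected} OQs, pipeline saw {got}"
                )
    return RecoveryReport(ok=not mismatches, n_compared=n, mismatches=mismatches)
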