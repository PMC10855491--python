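"""End-to-end orchestration: annotation -> catalog -> DE -> statistics -> report.

A run reads the annotation, derives promoters and gene bodies, builds the
consensus OQ catalog from the two condition BEDs, counts strictly-contained
OQs per region, stratifies genes by DE status, and emits descriptive
summaries plus presence (hypergeometric) and count (rank-sum) tests per
region class, as TSVs and one JSON report.  Reports carry the tool version,
the effective configuration and input checksums, and contain no timestamps:
reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .annotations import (
    GeneRecord,
    derive_promoters,
    gene_body_intervals,
    read_gene_annotation,
    write_bed6,
)
from .de_results import (
    partition_genes,
    read_de_table,
    tier_count_summary,
    write_partition,
)
from .enrichment import (
    count_comparison,
    length_comparison,
    presence_enrichment,
    summarize_oq_content,
)
from .gene_sets import read_alias_map, read_gene_list, tally_set
from .oq_catalog import (
    assign_contained,
    intersect_conditions,
    read_oq_bed,
    write_assignments,
    write_oq_bed,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

LOG_NAME = "g4enrich"
LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"

logger = logging.getLogger(LOG_NAME)


def configure_logging(json_lines: bool = False, level: int = logging.INFO) -> None:
    """Log to stderr, optionally as JSON lines for machine consumption."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _JsonFormatter(logging.Formatter):
            def format(self, record: logging.LogRecord) -> str:
                return json.dumps(
                    {"level": record.levelname, "msg": record.getMessage()}
                )

        handler.setFormatter(_JsonFormatter())
    else:
        handler.setFormatter(logging.Formatter(LOG_FORMAT))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    annotation: str
    oq_kplus: str
    oq_pds: str
    de_table: str
    outdir: str
    annotation_dialect: str = "tsv"
    chrom_sizes: str | None = None
    gene_lists: dict[str, str] = field(default_factory=dict)
    alias_map: str | None = None
    window: int = 1000
    alpha: float = 0.05
    tiers: tuple[int, ...] = (2, 5, 10)
    chroms: tuple[str, ...] | None = None
    strip_chr: bool = False
    strand_policy: str = "ignore"
    consensus_mode: str = "intersect"
    region_class: str = "both"  # "promoter" | "gene" | "both"


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file; keyword overrides win."""
    import yaml

    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "tiers" in data:
        data["tiers"] = tuple(data["tiers"])
    if data.get("chroms") is not None:
        data["chroms"] = tuple(data["chroms"])
    return RunConfig(**data)


def _md5(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def _infer_chrom_sizes(genes: Sequence[GeneRecord], window: int) -> dict[str, int]:
    """Upper bound per chromosome so no minus-strand promoter is clipped."""
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.interval.chrom] = max(
            sizes.get(g.interval.chrom, 0), g.interval.end + window
        )
    return sizes


def _tests_for_class(
    assignments, groups: Mapping[str, set[str]], region_class: str,
    genes: Sequence[GeneRecord], first_tier: int,
) -> dict:
    fc = f"DE_{first_tier}FC"
    tests: dict = {}
    for label in ("DE", fc):
        if groups.get(label):
            res = presence_enrichment(assignments, groups, region_class, label)
            tests[f"presence_{label}"] = {
                "N": res.N, "K": res.K, "n": res.n, "k": res.k,
                "p": res.p, "log10_p": res.log10_p,
            }
    for a, b in (("DE", "nonDE"), (fc, f"non{fc}")):
        if not (groups.get(a) and groups.get(b)):
            continue
        try:
            res = count_comparison(assignments, groups, region_class, a, b)
        except ValueError as exc:
            logger.warning("count comparison %s vs %s skipped: %s", a, b, exc)
            continue
        tests[f"counts_{a}_vs_{b}"] = {
            "W": res.W, "p": res.p, "n1": res.n1, "n2": res.n2,
            "method": res.method, "ties_present": res.ties_present,
        }
    if region_class == "gene" and groups.get("DE") and groups.get("nonDE"):
        res, mean_a, mean_b = length_comparison(
            genes, assignments, groups, "DE", "nonDE"
        )
        tests["length_DE_vs_nonDE"] = {
            "W": res.W, "p": res.p, "n1": res.n1, "n2": res.n2,
            "mean_length_DE": mean_a, "mean_length_nonDE": mean_b,
        }
    return tests


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle into ``outdir``.

    Returns the report dict (also written as ``report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("annotation", "oq_kplus", "oq_pds", "de_table"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} input not found: {path}")

    genes = read_gene_annotation(
        config.annotation,
        dialect=config.annotation_dialect,
        chrom_filter=config.chroms,
        strip_chr=config.strip_chr,
    )
    logger.info("annotation: %d genes read", len(genes))
    if config.chrom_sizes:
        chrom_sizes = _read_chrom_sizes(config.chrom_sizes)
    else:
        chrom_sizes = _infer_chrom_sizes(genes, config.window)
        logger.info("chromosome sizes not given; using per-chrom max(end)+window")
    promoters, skipped = derive_promoters(genes, chrom_sizes, window=config.window)
    logger.info("promoters: %d derived, %d clipped away", len(promoters), len(skipped))
    bodies = gene_body_intervals(genes)

    k_oqs = read_oq_bed(config.oq_kplus, "Kplus")
    pds_oqs = read_oq_bed(config.oq_pds, "PDS")
    consensus = intersect_conditions(k_oqs, pds_oqs, mode=config.consensus_mode)
    logger.info(
        "OQ catalog: %d K+, %d PDS, %d consensus intervals",
        len(k_oqs), len(pds_oqs), len(consensus),
    )

    records = read_de_table(config.de_table, alpha=config.alpha, tiers=config.tiers)
    partition = partition_genes(records, (g.gene_id for g in genes),
                                first_tier=config.tiers[0])
    if partition.unmatched:
        logger.warning(
            "%d DE-table ids not in annotation (first: %s)",
            len(partition.unmatched), partition.unmatched[:3],
        )
    logger.info(
        "DE: %d of %d genes significant at alpha=%g",
        len(partition["DE"]), len(partition.universe), config.alpha,
    )

    files: dict[str, str] = {}

    def _save(name: str, filename: str, writer) -> None:
        path = outdir / filename
        writer(path)
        files[name] = filename

    _save("promoters", "promoters.bed",
          lambda p: write_bed6(((pr.gene_id, pr.interval) for pr in promoters), p))
    _save("gene_bodies", "gene_bodies.bed", lambda p: write_bed6(bodies, p))
    _save("consensus", "consensus_oq.bed", lambda p: write_oq_bed(consensus, p))
    _save("partition", "partition.tsv", lambda p: write_partition(partition, p))

    classes = (
        ("promoter", "gene") if config.region_class == "both"
        else (config.region_class,)
    )
    first_tier = config.tiers[0]
    summary_groups = ["all", "DE", "nonDE", f"DE_{first_tier}FC", f"nonDE_{first_tier}FC"]
    region_sections: dict[str, dict] = {}
    for region_class in classes:
        regions = (
            [(p.gene_id, p.interval) for p in promoters]
            if region_class == "promoter" else bodies
        )
        assignments = assign_contained(
            regions, consensus, region_class, strand_policy=config.strand_policy
        )
        _save(f"assignments_{region_class}", f"assignments_{region_class}.tsv",
              lambda p, a=assignments: write_assignments(a, p))
        region_ids = {rid for rid, _ in regions}
        # promoters can be clipped away entirely; restrict groups to the class
        groups = {
            label: partition.groups[label] & region_ids for label in summary_groups
        }
        summaries = summarize_oq_content(assignments, groups, region_class)
        n_with = {s.group: s.n_with_oq for s in summaries}
        logger.info(
            "%s: %d regions, %d with >=1 OQ",
            region_class, len(assignments), n_with.get("all", 0),
        )
        region_sections[region_class] = {
            "summaries": [s.as_dict() for s in summaries],
            "tests": _tests_for_class(
                assignments, groups, region_class, genes, first_tier
            ),
        }

    tallies = []
    if config.gene_lists:
        alias = read_alias_map(config.alias_map) if config.alias_map else None
        for name, path in sorted(config.gene_lists.items()):
            tally = tally_set(name, read_gene_list(path), records,
                              tier=first_tier, alias_map=alias)
            tallies.append(tally.as_dict())

    # reports must be byte-identical across reruns wherever the inputs are
    # identical in content: record basenames + checksums, not absolute paths
    cfg = asdict(config)
    cfg.pop("outdir")
    for key in ("annotation", "oq_kplus", "oq_pds", "de_table",
                "chrom_sizes", "alias_map"):
        if cfg.get(key):
            cfg[key] = Path(cfg[key]).name
    cfg["gene_lists"] = {k: Path(v).name for k, v in cfg["gene_lists"].items()}
    report = {
        "tool": {"name": "g4enrich", "version": __version__},
        "config": cfg,
        "inputs": {
            name: _md5(getattr(config, name))
            for name in ("annotation", "oq_kplus", "oq_pds", "de_table")
        },
        "stages": {
            "genes_read": len(genes),
            "promoters_derived": len(promoters),
            "promoters_clipped_away": len(skipped),
            "oq_kplus": len(k_oqs),
            "oq_pds": len(pds_oqs),
            "consensus_oqs": len(consensus),
            "de_genes": len(partition["DE"]),
            "de_unmatched": len(partition.unmatched),
        },
        "de_tier_summary": tier_count_summary(records, config.tiers),
        "region_classes": region_sections,
        "gene_set_tallies": tallies,
        "files": files,
    }
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return report
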