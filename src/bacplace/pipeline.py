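"""End-to-end orchestration: hits -> placements -> coverage, gene
coverage and variant reports."""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as bio
from .coverage import (
    coverage_table,
    aligned_bases_per_chromosome,
    gene_coverage,
    gene_coverage_summary,
)
from .placement import (
    DEFAULT_CLONE_REGEX,
    candidate_spans,
    category_counts,
    estimate_insert_stats,
    filter_hits,
    group_clones,
    parse_read_id,
    place_clones,
    summarize_library,
)
from .model import EndRead
from .variants import call_variants

logger = logging.getLogger(__name__)

_THRESHOLD_FIELDS = ("min_span", "min_identity", "sd_window", "var_min_match")


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run; serializable to
    and from a YAML mapping with unknown keys rejected."""

    genome: str = ""
    hits: str = ""
    hits_dialect: str = "tabular"
    genes: str = ""
    genes_format: str = "bed"
    alignments: str = ""  # SAM with per-base information, for variants
    reference_fasta: str = ""
    library_label: str = "library"
    clone_regex: str = DEFAULT_CLONE_REGEX
    min_span: int = 100
    min_identity: float = 95.0
    sd_window: float = 3.0
    max_iter: int = 20
    tol: float = 0.5
    var_min_identity: float = 92.0
    var_min_len_frac: float = 0.80
    var_min_match: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _THRESHOLD_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PlacementResult:
    stats: "object"
    placements: list
    summary: "object"
    reads: list
    filtered: list


def run_placement(config: RunConfig) -> PlacementResult:
    """Load genome and hits, estimate insert statistics and place
    every clone."""
    genome = bio.load_genome(config.genome)
    raw_hits = bio.load_hits(config.hits, config.hits_dialect, genome)
    filtered = filter_hits(raw_hits, config.min_span, config.min_identity)
    # read length proxied by the longest alignment of the read
    max_alen: dict[str, int] = {}
    for h in raw_hits:
        max_alen[h.read_id] = max(max_alen.get(h.read_id, 0), h.aligned_length)
    reads = []
    for rid in sorted(max_alen):
        clone_id, end_label = parse_read_id(rid, config.clone_regex)
        reads.append(EndRead(rid, clone_id, end_label, max_alen[rid]))
    clones = group_clones(reads, filtered)
    spans = candidate_spans(clones)
    stats = estimate_insert_stats(spans, config.sd_window, config.max_iter, config.tol)
    placements = place_clones(clones, stats)
    summary = summarize_library(reads, filtered, placements)
    logger.info(
        "placement: thresholds min_span=%d min_identity=%.2f sd_window=%.1f; "
        "insert mean=%.1f sd=%.1f; categories=%s",
        config.min_span,
        config.min_identity,
        config.sd_window,
        stats.mean,
        stats.sd,
        category_counts(placements),
    )
    return PlacementResult(stats, placements, summary, reads, filtered)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write summary.tsv, coverage.tsv,
    genecov.tsv, placements.bed, placements.tsv, insert_stats.json,
    variants.vcf and run.log under ``outdir``.

    Outputs are written to a staging directory and moved into place
    only on success, so a failed run leaves no partial outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".bacplace-", dir=outdir))
    try:
        written = _run_pipeline_into(config, staging)
        for f in written:
            shutil.move(str(staging / f), str(outdir / f))
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return {"outputs": [str(outdir / f) for f in written]}


def _run_pipeline_into(config: RunConfig, outdir: Path) -> list[str]:
    log_lines: list[str] = []
    genome = bio.load_genome(config.genome)
    result = run_placement(config)
    written: list[str] = []

    with open(outdir / "insert_stats.json", "w") as fh:
        json.dump(result.stats.to_dict(), fh, indent=1, sort_keys=True)
    written.append("insert_stats.json")

    bio.write_tracks(result.placements, outdir / "placements.bed")
    written.append("placements.bed")
    bio.write_table(
        [
            {
                "clone_id": p.clone_id,
                "category": p.category,
                "chromosome": p.chromosome or "",
                "start": "" if p.start is None else p.start,
                "end": "" if p.end is None else p.end,
                "strand": p.strand if p.placed else "",
            }
            for p in result.placements
        ],
        outdir / "placements.tsv",
    )
    written.append("placements.tsv")

    bio.write_table([result.summary.to_dict()], outdir / "summary.tsv")
    written.append("summary.tsv")

    read_lengths = {r.read_id: r.read_length for r in result.reads}
    aligned = aligned_bases_per_chromosome(result.placements, read_lengths)
    rows = coverage_table(result.placements, genome, aligned)
    bio.write_table([r.to_dict() for r in rows], outdir / "coverage.tsv")
    written.append("coverage.tsv")

    if config.genes:
        genes = bio.load_genes(config.genes, config.genes_format)
        calls = gene_coverage(result.placements, genes)
        bio.write_table(
            [{"gene_id": c.gene_id, "status": c.status} for c in calls],
            outdir / "genecov.tsv",
        )
        written.append("genecov.tsv")
        log_lines.append(f"gene coverage: {gene_coverage_summary(calls)}")

    if config.alignments and config.reference_fasta:
        reference = bio.load_fasta_sequences(config.reference_fasta)
        reads = bio.load_aligned_reads(config.alignments)
        calls = call_variants(
            reads,
            reference,
            config.var_min_identity,
            config.var_min_len_frac,
            config.var_min_match,
        )
        bio.write_variants(calls, outdir / "variants.vcf", reference)
        written.append("variants.vcf")
        n_snp = sum(1 for c in calls if c.vtype == "SNP")
        log_lines.append(f"variants: {n_snp} SNPs, {len(calls) - n_snp} DIPs")

    log_lines.insert(
        0,
        "thresholds: "
        + " ".join(
            f"{k}={getattr(config, k)}"
            for k in (
                "min_span",
                "min_identity",
                "sd_window",
                "var_min_identity",
                "var_min_len_frac",
                "var_min_match",
            )
        ),
    )
    log_lines.insert(1, f"categories: {category_counts(result.placements)}")
    log_lines.insert(
        2,
        f"insert stats: mean={result.stats.mean:.1f} sd={result.stats.sd:.1f} "
        f"n_used={result.stats.n_used} n_rejected={result.stats.n_rejected} "
        f"iterations={result.stats.iterations}",
    )
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    written.append("run.log")
    return written
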