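"""Physical genome coverage and gene coverage from placed clones.

Coverage is reported per chromosome in the shape of a clone-resource
coverage table:

* non-redundant clone length — the footprint of the union of placed
  clone intervals (each base counted once);
* clone-length total — the sum of clone spans (overlaps counted
  multiply);
* clone depth — clone-length total divided by chromosome length;
* % total coverage — non-redundant length as a percentage of the
  chromosome length.

Only placed clones (``unique_pair`` and ``rescued``) contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .model import GeneRecord, GenomeIndex
from .placement import Placement
from .util import round_half_up

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge 0-based half-open intervals into disjoint sorted
    intervals; touching intervals are coalesced."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def footprint(intervals: Iterable[Interval]) -> int:
    """Total number of bases covered at least once."""
    return sum(e - s for s, e in merge_intervals(intervals))


def gap_intervals(intervals: Iterable[Interval], chrom_length: int) -> list[Interval]:
    """Complement of the merged intervals within [0, chrom_length)."""
    gaps = []
    pos = 0
    for s, e in merge_intervals(intervals):
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < chrom_length:
        gaps.append((pos, chrom_length))
    return gaps


@dataclass(frozen=True)
class CoverageRow:
    """One chromosome's (or aggregate's) coverage statistics.

    ``clone_depth`` and ``pct_total_coverage`` are the full-precision
    ratios; the ``*_printed`` properties give the rounded presentation
    values (half-up, two decimals for chromosome rows)."""

    chromosome: str
    total_chr_length: int
    nonredundant_clone_length: int
    clone_length_total: int
    passed_aligned_sequence: int
    ndigits: int = 2

    def __post_init__(self) -> None:
        if self.nonredundant_clone_length > self.total_chr_length:
            raise ValueError(
                f"{self.chromosome}: non-redundant length exceeds chromosome length"
            )
        if self.nonredundant_clone_length > self.clone_length_total:
            raise ValueError(
                f"{self.chromosome}: non-redundant length exceeds clone-length total"
            )

    @property
    def clone_depth(self) -> float:
        return self.clone_length_total / self.total_chr_length

    @property
    def pct_total_coverage(self) -> float:
        return 100.0 * self.nonredundant_clone_length / self.total_chr_length

    @property
    def clone_depth_printed(self) -> float:
        return round_half_up(self.clone_depth, self.ndigits)

    @property
    def pct_total_coverage_printed(self) -> float:
        return round_half_up(self.pct_total_coverage, self.ndigits)

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "total_chr_length": self.total_chr_length,
            "nonredundant_clone_length": self.nonredundant_clone_length,
            "clone_length_total": self.clone_length_total,
            "passed_aligned_sequence": self.passed_aligned_sequence,
            "clone_depth": self.clone_depth_printed,
            "pct_total_coverage": self.pct_total_coverage_printed,
        }


def coverage_table(
    placements: Sequence[Placement],
    genome: GenomeIndex,
    aligned_bases: Mapping[str, int] | None = None,
) -> list[CoverageRow]:
    """Per-chromosome coverage rows in genome order, followed by
    aggregate rows.

    ``aligned_bases`` maps chromosome name to the total number of
    passed, mapped sequenced bases (the sum of aligned end-read
    lengths), reported verbatim in the table.

    Aggregates (rounded to one decimal) are appended for each
    chromosome class present, for the whole genome, and for the genome
    excluding chromosomes with no placed clone coverage class Y
    (labelled ``genome_excl_Y``) so both denominators are available.
    """
    aligned_bases = aligned_bases or {}
    per_chrom: dict[str, list[Interval]] = {e.name: [] for e in genome}
    for p in placements:
        if not p.placed:
            continue
        if p.chromosome not in per_chrom:
            raise ValueError(f"placement on unknown chromosome {p.chromosome!r}")
        per_chrom[p.chromosome].append((p.start, p.end))
    rows = []
    for e in genome:
        ivs = per_chrom[e.name]
        rows.append(
            CoverageRow(
                chromosome=e.name,
                total_chr_length=e.length,
                nonredundant_clone_length=footprint(ivs),
                clone_length_total=sum(b - a for a, b in ivs),
                passed_aligned_sequence=int(aligned_bases.get(e.name, 0)),
            )
        )
    rows.extend(aggregate_rows(rows, genome))
    return rows


def aggregate_rows(rows: Sequence[CoverageRow], genome: GenomeIndex) -> list[CoverageRow]:
    """Aggregate coverage rows per chromosome class, genome-wide, and
    genome-wide excluding Y; depth/coverage rounded to one decimal."""
    by_name = {r.chromosome: r for r in rows if r.chromosome in genome}

    def agg(label: str, names: list[str]) -> CoverageRow | None:
        if not names:
            return None
        sel = [by_name[n] for n in names]
        return CoverageRow(
            chromosome=label,
            total_chr_length=sum(r.total_chr_length for r in sel),
            nonredundant_clone_length=sum(r.nonredundant_clone_length for r in sel),
            clone_length_total=sum(r.clone_length_total for r in sel),
            passed_aligned_sequence=sum(r.passed_aligned_sequence for r in sel),
            ndigits=1,
        )

    out = []
    for cls in ("autosome", "X", "Y", "other"):
        # suffixed so class aggregates cannot collide with a
        # chromosome actually named "X" or "Y"
        row = agg(f"{cls}_total", [e.name for e in genome if e.chrom_class == cls])
        if row is not None:
            out.append(row)
    out.append(agg("genome", [e.name for e in genome]))
    non_y = [e.name for e in genome if e.chrom_class != "Y"]
    if len(non_y) != len(genome):
        out.append(agg("genome_excl_Y", non_y))
    return [r for r in out if r is not None]


@dataclass(frozen=True)
class GeneCoverageCall:
    gene_id: str
    status: str  # full | partial | gap


def gene_coverage(
    placements: Sequence[Placement],
    genes: Sequence[GeneRecord],
    full_requires_single_clone: bool = True,
) -> list[GeneCoverageCall]:
    """Classify each gene against the placed clones.

    ``full``: some single clone interval contains the whole gene
    (when ``full_requires_single_clone``; otherwise containment in the
    merged clone union suffices).  ``gap``: no clone interval
    intersects the gene.  ``partial``: anything in between.
    """
    trees: dict[str, IntervalTree] = {}
    for p in placements:
        if p.placed:
            trees.setdefault(p.chromosome, IntervalTree()).addi(p.start, p.end)
    merged = {
        chrom: merge_intervals([(iv.begin, iv.end) for iv in tree])
        for chrom, tree in trees.items()
    }
    calls = []
    for g in genes:
        tree = trees.get(g.chromosome)
        overlapping = tree.overlap(g.start, g.end) if tree is not None else set()
        if not overlapping:
            status = "gap"
        elif full_requires_single_clone:
            status = (
                "full"
                if any(iv.begin <= g.start and g.end <= iv.end for iv in overlapping)
                else "partial"
            )
        else:
            status = (
                "full"
                if any(s <= g.start and g.end <= e for s, e in merged.get(g.chromosome, []))
                else "partial"
            )
        calls.append(GeneCoverageCall(g.gene_id, status))
    return calls


def gene_coverage_summary(calls: Sequence[GeneCoverageCall]) -> dict[str, int]:
    out = {"full": 0, "partial": 0, "gap": 0, "total": len(calls)}
    for c in calls:
        out[c.status] += 1
    return out


def compare_gene_coverage(
    calls_a: Sequence[GeneCoverageCall], calls_b: Sequence[GeneCoverageCall]
) -> dict[str, int]:
    """Cross-library intersection counts over a shared gene set:
    genes partial in both libraries and genes absent (gap) in both."""
    a = {c.gene_id: c.status for c in calls_a}
    b = {c.gene_id: c.status for c in calls_b}
    shared = set(a) & set(b)
    return {
        "partial_in_both": sum(1 for g in shared if a[g] == "partial" and b[g] == "partial"),
        "gap_in_both": sum(1 for g in shared if a[g] == "gap" and b[g] == "gap"),
        "shared_genes": len(shared),
    }


def aligned_bases_per_chromosome(
    placements: Sequence[Placement],
    read_lengths: Mapping[str, int],
) -> dict[str, int]:
    """Sum of aligned end-read lengths per chromosome over placed
    clones, i.e. the sequenced bases that passed QC and mapped."""
    out: dict[str, int] = {}
    for p in placements:
        if not p.placed:
            continue
        for rid in p.hit_refs:
            out[p.chromosome] = out.get(p.chromosome, 0) + int(read_lengths.get(rid, 0))
    return out
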