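"""Synthetic clone-library simulator with known ground truth.

Generates a random reference genome (optionally with repeat families
that induce genuine multi-mapping), a BAC clone library sampled from a
diverged copy of that genome (planted SNPs and DIPs), paired end reads
from the insert extremities, and the alignment hits those reads would
produce — in both the tabular and SAM dialects.  Every emitted file is
deterministic in the seed, and a :class:`GroundTruth` records true
clone positions, read origins, planted variants and the structurally
expected placement category of every clone, so each pipeline stage can
be checked against a known answer.

Defaults emulate a library of ~150 kb inserts end-sequenced to ~700 bp
(with a 205 kb preset for larger-insert libraries), a 3% insertless
clone fraction, and strain divergence of roughly one SNP per 1.2 kb —
scaled onto desk-size chromosomes of a few megabases.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import AlignedRead, AlignmentHit, ChromEntry, EndRead, GenomeIndex, cigar_to_string
from .placement import DEFAULT_CLONE_REGEX

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Lengths are base pairs; rates are per base.  The X chromosome (the
    last one, when ``include_x``) can be undersampled via ``x_weight``
    to emulate a male library donor.
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (2_000_000, 1_500_000, 1_000_000)
    include_x: bool = True
    x_weight: float = 1.0
    n_clones: int = 500
    insert_mean: float = 150_000.0
    insert_sd: float = 15_000.0
    read_length_mean: float = 694.0
    read_length_sd: float = 30.0
    substitution_rate: float = 0.001  # sequencing error, post-QC
    snp_rate: float = 8e-4  # strain divergence vs reference
    dip_rate: float = 7e-5
    dip_max_len: int = 6
    insertless_fraction: float = 0.03
    n_repeat_families: int = 8
    repeat_length: int = 20_000
    repeat_copies: int = 3
    n_genes: int = 100
    gene_length_mean: float = 20_000.0
    end_labels: tuple[str, str] = ("T7", "SP6")

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.snp_rate, self.dip_rate,
                     self.insertless_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not self.insert_mean - 3 * self.insert_sd > 2 * self.read_length_mean:
            raise ValueError(
                "insert mean - 3 SD must exceed twice the read length; "
                "the two end reads of a clone may not overlap"
            )

    @classmethod
    def large_insert_preset(cls, **overrides) -> "SimConfig":
        """Preset for a larger-insert, male-donor library: 205 kb mean
        insert, 1% insertless clones, X sampled at half weight."""
        base = dict(
            insert_mean=205_000.0,
            insert_sd=20_500.0,
            read_length_mean=719.0,
            insertless_fraction=0.01,
            x_weight=0.5,
        )
        base.update(overrides)
        return cls(**base)

    def chromosome_names(self) -> list[str]:
        n = len(self.chromosome_lengths)
        if self.include_x and n >= 2:
            return [str(i + 1) for i in range(n - 1)] + ["X"]
        return [str(i + 1) for i in range(n)]


@dataclass(frozen=True)
class RepeatCopy:
    family: int
    chromosome: str
    start: int
    end: int


@dataclass
class PlantedVariant:
    chromosome: str
    position: int  # 0-based reference position
    ref_allele: str
    alt_allele: str
    vtype: str  # SNP | DIP

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimRead:
    """One simulated end read with its true alignment."""

    read: EndRead
    sequence: str  # as sequenced (reverse-complemented for - strand)
    chromosome: str | None = None
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    cigar: list[tuple[str, int]] = field(default_factory=list)
    aligned_query: str = ""  # reference-orientation query


@dataclass
class CloneTruth:
    clone_id: str
    chromosome: str | None
    start: int
    end: int
    expected_category: str  # unique_pair | rescued | both_multiple | insertless


@dataclass
class GroundTruth:
    clones: list[CloneTruth] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)
    repeat_copies: list[RepeatCopy] = field(default_factory=list)

    def expected_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clones:
            out[c.expected_category] = out.get(c.expected_category, 0) + 1
        return out

    def variant_keys(self) -> set[tuple]:
        return {
            (v.chromosome, v.position, v.ref_allele, v.alt_allele, v.vtype)
            for v in self.variants
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clones": [dataclasses.asdict(c) for c in self.clones],
            "variants": [v.to_dict() for v in self.variants],
            "repeat_copies": [dataclasses.asdict(r) for r in self.repeat_copies],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------- genome


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], GenomeIndex, list[RepeatCopy]]:
    """Random genome of i.i.d. bases with repeat-family copies pasted
    at recorded locations (identical copies, so reads from inside a
    copy genuinely multi-map)."""
    rng = np.random.default_rng([config.seed, 0])
    names = config.chromosome_names()
    seqs: dict[str, str] = {}
    for name, length in zip(names, config.chromosome_lengths):
        seqs[name] = "".join(BASES[rng.integers(0, 4, size=length)])
    copies: list[RepeatCopy] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for fam in range(config.n_repeat_families):
        if config.repeat_copies < 1 or config.repeat_length < 1:
            continue
        fam_seq = "".join(BASES[rng.integers(0, 4, size=config.repeat_length)])
        placed = 0
        attempts = 0
        while placed < config.repeat_copies and attempts < 1000:
            attempts += 1
            ci = int(rng.integers(0, len(names)))
            name = names[ci]
            length = config.chromosome_lengths[ci]
            if length <= config.repeat_length + 2:
                continue
            start = int(rng.integers(1, length - config.repeat_length - 1))
            end = start + config.repeat_length
            if any(s < end and start < e for s, e in occupied[name]):
                continue
            seqs[name] = seqs[name][:start] + fam_seq + seqs[name][end:]
            occupied[name].append((start, end))
            copies.append(RepeatCopy(fam, name, start, end))
            placed += 1
    entries = []
    for name, length in zip(names, config.chromosome_lengths):
        cls = "X" if (config.include_x and name == "X") else "autosome"
        entries.append(ChromEntry(name, length, cls))
    return seqs, GenomeIndex(entries), copies


def plant_variants(seqs: dict[str, str], config: SimConfig) -> list[PlantedVariant]:
    """Plant strain-divergence SNPs and DIPs at recorded reference
    positions, spaced at least 20 bp apart so events never overlap."""
    rng = np.random.default_rng([config.seed, 1])
    plants: list[PlantedVariant] = []
    for chrom, seq in seqs.items():
        n_snp = rng.binomial(len(seq), config.snp_rate)
        n_dip = rng.binomial(len(seq), config.dip_rate)
        positions = rng.choice(
            np.arange(100, len(seq) - 100), size=min(n_snp + n_dip, len(seq) // 50),
            replace=False,
        )
        positions = np.sort(positions)
        keep = []
        last = -10_000
        for p in positions:
            if p - last >= 20:
                keep.append(int(p))
                last = int(p)
        chrom_plants: list[PlantedVariant] = []
        for i, p in enumerate(keep):
            ref_base = seq[p]
            if i < min(n_dip, len(keep)):  # first few become DIPs
                length = int(rng.integers(1, config.dip_max_len + 1))
                if rng.random() < 0.5:  # deletion relative to reference
                    chrom_plants.append(
                        PlantedVariant(chrom, p, seq[p : p + length], "", "DIP")
                    )
                else:  # insertion
                    ins = "".join(BASES[rng.integers(0, 4, size=length)])
                    chrom_plants.append(PlantedVariant(chrom, p, "", ins, "DIP"))
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                chrom_plants.append(PlantedVariant(chrom, p, ref_base, alt, "SNP"))
        chrom_plants.sort(key=lambda v: v.position)
        plants.extend(chrom_plants)
    return plants


# ---------------------------------------------------------- read drawing


def _build_alignment(
    seq: str, plants: Sequence[PlantedVariant], ref_start: int, n_query: int
) -> tuple[str, list[tuple[str, int]], int]:
    """Walk the reference from ``ref_start`` applying planted variants
    until ``n_query`` read bases are collected.

    Returns (query, cigar, ref_end).  Insertions apply before their
    reference position; deletions skip reference bases.
    """
    by_pos = {p.position: p for p in plants}
    query: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    pos = ref_start
    while len(query) < n_query and pos < len(seq):
        plant = by_pos.get(pos)
        if plant is not None and plant.vtype == "DIP" and plant.ref_allele == "":
            take = min(len(plant.alt_allele), n_query - len(query))
            query.extend(plant.alt_allele[:take])
            push("I", take)
            if len(query) >= n_query:
                break
            by_pos = dict(by_pos)
            del by_pos[pos]  # insertion applied once; fall through to ref base
            continue
        if plant is not None and plant.vtype == "DIP" and plant.alt_allele == "":
            push("D", len(plant.ref_allele))
            pos += len(plant.ref_allele)
            continue
        if plant is not None and plant.vtype == "SNP":
            query.append(plant.alt_allele)
        else:
            query.append(seq[pos])
        push("M", 1)
        pos += 1
    return "".join(query), ops, pos


def _plants_in(plants: Sequence[PlantedVariant], chrom: str, lo: int, hi: int) -> list[PlantedVariant]:
    return [
        p
        for p in plants
        if p.chromosome == chrom and lo <= p.position < hi + 10
    ]


def _apply_sequencing_errors(
    query: str, rng: np.random.Generator, rate: float
) -> str:
    if rate <= 0 or not query:
        return query
    n_err = rng.binomial(len(query), rate)
    if n_err == 0:
        return query
    pos = rng.choice(len(query), size=n_err, replace=False)
    chars = list(query)
    for p in pos:
        chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
    return "".join(chars)


def simulate_library(
    seqs: dict[str, str],
    genome: GenomeIndex,
    config: SimConfig,
    plants: Sequence[PlantedVariant] | None = None,
    repeat_copies: Sequence[RepeatCopy] | None = None,
) -> tuple[list[SimRead], GroundTruth]:
    """Draw a clone library and its end reads.

    Clone starts are uniform per chromosome (chromosomes weighted by
    length, the X additionally by ``x_weight``); spans are
    Normal(mean, sd^2) truncated to fit; the two end reads come from
    opposite strands at the insert extremities.  Insertless clones emit
    unmappable random reads.
    """
    plants = list(plants) if plants is not None else []
    repeat_copies = list(repeat_copies) if repeat_copies is not None else []
    names = genome.names
    weights = np.array(
        [
            e.length * (config.x_weight if e.chrom_class == "X" else 1.0)
            for e in genome
        ],
        dtype=float,
    )
    weights /= weights.sum()
    la, lb = config.end_labels
    sim_reads: list[SimRead] = []
    truth = GroundTruth(variants=list(plants), repeat_copies=list(repeat_copies))

    def read_length(rng: np.random.Generator) -> int:
        return max(50, int(round(rng.normal(config.read_length_mean, config.read_length_sd))))

    def is_multi(chrom: str, lo: int, hi: int) -> bool:
        for rc in repeat_copies:
            if rc.chromosome == chrom and rc.start <= lo and hi <= rc.end:
                n_copies = sum(1 for o in repeat_copies if o.family == rc.family)
                return n_copies > 1
        return False

    for i in range(config.n_clones):
        rng = np.random.default_rng([config.seed, 2, i])
        clone_id = f"bSIM{i:06d}"
        if rng.random() < config.insertless_fraction:
            for label in (la, lb):
                L = read_length(rng)
                seq = "".join(BASES[rng.integers(0, 4, size=L)])
                sim_reads.append(
                    SimRead(read=EndRead(f"{clone_id}.{label}", clone_id, label, L), sequence=seq)
                )
            truth.clones.append(CloneTruth(clone_id, None, 0, 0, "insertless"))
            continue
        ci = int(rng.choice(len(names), p=weights))
        chrom = names[ci]
        seq = seqs[chrom]
        for _ in range(100):
            span = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            if 2 * int(config.read_length_mean + 5 * config.read_length_sd) < span <= len(seq):
                break
        else:
            span = min(int(config.insert_mean), len(seq))
        start = int(rng.integers(0, len(seq) - span + 1))
        end_target = start + span
        # left end read, forward strand
        l_len = read_length(rng)
        l_plants = _plants_in(plants, chrom, start, start + l_len + 50)
        l_query, l_cigar, l_end = _build_alignment(seq, l_plants, start, l_len)
        l_query = _apply_sequencing_errors(l_query, rng, config.substitution_rate)
        # right end read, reverse strand; choose its reference start so
        # the alignment ends at the clone end, adjusting for indels
        r_len = read_length(rng)
        r_start = end_target - r_len
        for _ in range(5):
            r_plants = _plants_in(plants, chrom, r_start - 10, end_target)
            r_query, r_cigar, r_end = _build_alignment(seq, r_plants, r_start, r_len)
            if r_end == end_target:
                break
            r_start += end_target - r_end
            if r_start < 0:
                r_start = 0
                break
        r_query = _apply_sequencing_errors(r_query, rng, config.substitution_rate)
        clone_end = r_end
        sim_reads.append(
            SimRead(
                read=EndRead(f"{clone_id}.{la}", clone_id, la, len(l_query)),
                sequence=l_query,
                chromosome=chrom,
                ref_start=start,
                ref_end=l_end,
                strand="+",
                cigar=l_cigar,
                aligned_query=l_query,
            )
        )
        sim_reads.append(
            SimRead(
                read=EndRead(f"{clone_id}.{lb}", clone_id, lb, len(r_query)),
                sequence=revcomp(r_query),
                chromosome=chrom,
                ref_start=r_start,
                ref_end=r_end,
                strand="-",
                cigar=r_cigar,
                aligned_query=r_query,
            )
        )
        left_multi = is_multi(chrom, start, l_end)
        right_multi = is_multi(chrom, r_start, r_end)
        if left_multi and right_multi:
            expected = "both_multiple"
        elif left_multi or right_multi:
            expected = "rescued"
        else:
            expected = "unique_pair"
        truth.clones.append(CloneTruth(clone_id, chrom, start, clone_end, expected))
    return sim_reads, truth


# ------------------------------------------------------------------ hits


def _identity_of(query: str, ref_seg_getter, cigar, ref_start: int) -> tuple[int, int]:
    """(matches, aligned columns) of a query against reference text."""
    matches = cols = 0
    qpos, rpos = 0, ref_start
    for op, n in cigar:
        if op == "M":
            ref = ref_seg_getter(rpos, rpos + n)
            for i in range(n):
                cols += 1
                if query[qpos + i] == ref[i]:
                    matches += 1
            qpos += n
            rpos += n
        elif op == "I":
            qpos += n
        elif op == "D":
            rpos += n
    return matches, cols


def simulate_hits(
    sim_reads: Sequence[SimRead],
    seqs: dict[str, str],
    repeat_copies: Sequence[RepeatCopy],
) -> tuple[list[AlignmentHit], list[AlignedRead]]:
    """Derive the alignment hits the simulated reads would produce.

    Each mappable read yields its true-origin hit; a read lying fully
    inside a repeat copy additionally yields one hit per homologous
    copy, with identity recomputed against that copy's sequence.
    """
    hits: list[AlignmentHit] = []
    aligned: list[AlignedRead] = []
    by_family: dict[int, list[RepeatCopy]] = {}
    for rc in repeat_copies:
        by_family.setdefault(rc.family, []).append(rc)

    for sr in sim_reads:
        if sr.chromosome is None:
            continue
        placements = [(sr.chromosome, sr.ref_start)]
        for rc in repeat_copies:
            if (
                rc.chromosome == sr.chromosome
                and rc.start <= sr.ref_start
                and sr.ref_end <= rc.end
            ):
                offset = sr.ref_start - rc.start
                for other in by_family[rc.family]:
                    if other is rc:
                        continue
                    placements.append((other.chromosome, other.start + offset))
                break
        for chrom, rstart in placements:
            seq = seqs[chrom]
            matches, cols = _identity_of(
                sr.aligned_query, lambda a, b: seq[a:b], sr.cigar, rstart
            )
            # identical expression to the SAM loader's NM-derived
            # identity, so both dialects load bit-equal hits
            identity = 100.0 * matches / cols if cols else 0.0
            ref_span = sum(n for op, n in sr.cigar if op in "MD")
            hits.append(
                AlignmentHit(
                    read_id=sr.read.read_id,
                    chromosome=chrom,
                    start=rstart,
                    end=rstart + ref_span,
                    strand=sr.strand,
                    identity=identity,
                    aligned_length=cols,
                    score=float(matches),
                )
            )
            aligned.append(
                AlignedRead(
                    read_id=sr.read.read_id,
                    chromosome=chrom,
                    start=rstart,
                    strand=sr.strand,
                    cigar=list(sr.cigar),
                    query=sr.aligned_query,
                    identity=100.0 * matches / cols if cols else 0.0,
                    score=float(matches),
                )
            )
    return hits, aligned


# ----------------------------------------------------------- file output


def write_sam(
    aligned: Sequence[AlignedRead],
    genome: GenomeIndex,
    path: str | Path,
) -> None:
    """Write alignments as plain-text SAM with NM and AS tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": e.name, "LN": e.length} for e in genome],
    }
    ref_ids = {e.name: i for i, e in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ar in aligned:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = ar.read_id
            rec.query_sequence = ar.query
            rec.flag = 16 if ar.strand == "-" else 0
            rec.reference_id = ref_ids[ar.chromosome]
            rec.reference_start = ar.start
            rec.mapping_quality = 60
            rec.cigarstring = cigar_to_string(ar.cigar)
            matches = round(ar.identity * ar.match_length / 100.0)
            mismatches = ar.match_length - matches
            indel = sum(n for op, n in ar.cigar if op in "ID")
            rec.set_tag("NM", int(mismatches + indel))
            rec.set_tag("AS", int(ar.score))
            out.write(rec)


def write_reads_fasta(sim_reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sr in sim_reads:
            fh.write(f">{sr.read.read_id}\n{sr.sequence}\n")


def emit_fixture_set(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Run the full simulator and write genome.fa, genome.tsv,
    reads.fa, hits.tsv, hits.sam and truth.json under ``outdir``."""
    from . import io as bio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs, genome, repeats = simulate_genome(config)
    plants = plant_variants(seqs, config)
    sim_reads, truth = simulate_library(seqs, genome, config, plants, repeats)
    hits, aligned = simulate_hits(sim_reads, seqs, repeats)
    bio.write_fasta(seqs, outdir / "genome.fa")
    bio.write_genome_index(genome, outdir / "genome.tsv")
    write_reads_fasta(sim_reads, outdir / "reads.fa")
    bio.write_hits_tabular(hits, outdir / "hits.tsv")
    write_sam(aligned, genome, outdir / "hits.sam")
    truth.to_json(outdir / "truth.json")
    return truth


def simulate_genes(genome: GenomeIndex, config: SimConfig) -> list:
    """Random gene annotation for coverage tests: exponential-ish
    lengths around ``gene_length_mean``, uniform placement."""
    from .model import GeneRecord

    rng = np.random.default_rng([config.seed, 3])
    genes = []
    lengths = np.array([e.length for e in genome], dtype=float)
    p = lengths / lengths.sum()
    for i in range(config.n_genes):
        ci = int(rng.choice(len(genome), p=p))
        entry = genome.entries[ci]
        glen = max(200, int(rng.exponential(config.gene_length_mean)))
        glen = min(glen, entry.length - 2)
        start = int(rng.integers(0, entry.length - glen))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"GENE{i:05d}", entry.name, start, start + glen, strand))
    return genes
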