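"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open everywhere; 1-based
inclusive conventions (tabular hits, GFF3, SAM, VCF) are converted at
these boundaries and nowhere else.  Column definitions for the
non-standard tabular formats are documented in FORMATS.md.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

from .model import (
    AlignedRead,
    AlignmentHit,
    ChromEntry,
    GeneRecord,
    GenomeIndex,
    cigar_from_string,
    default_chrom_class,
)
from .placement import Placement
from .variants import VariantCall

logger = logging.getLogger(__name__)

TABULAR_HIT_COLUMNS = (
    "read_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "identity",
    "aligned_length",
    "score",
)


# ---------------------------------------------------------------- genome


def load_genome(path: str | Path, classify=default_chrom_class) -> GenomeIndex:
    """Load a genome index from FASTA or a two-column name/length table.

    The file type is sniffed from the first non-blank character ('>'
    means FASTA).  Chromosome classes are assigned by ``classify``
    (default: X/Y by name, everything else autosome).
    """
    path = Path(path)
    with open(path) as fh:
        head = ""
        for line in fh:
            if line.strip():
                head = line
                break
    entries: list[ChromEntry] = []
    if head.startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            entries.append(ChromEntry(rec.id, len(rec.seq), classify(rec.id)))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected name and length")
                name, length = fields[0], int(fields[1])
                entries.append(ChromEntry(name, length, classify(name)))
    names = [e.name for e in entries]
    if len(names) != len(set(names)):
        raise ValueError(f"{path}: duplicate sequence names")
    return GenomeIndex(entries)


def write_genome_index(genome: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in genome:
            fh.write(f"{e.name}\t{e.length}\n")


def load_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Load FASTA records as plain upper-case strings keyed by id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------ hits


def _hits_from_tabular(path: Path, genome: GenomeIndex | None) -> tuple[list[AlignmentHit], int]:
    hits: list[AlignmentHit] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(TABULAR_HIT_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(TABULAR_HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            read_id, chrom, start, end, strand, ident, alen, score = fields
            if genome is not None and chrom not in genome:
                skipped += 1
                continue
            # tabular dialect is 1-based inclusive
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    chromosome=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    identity=float(ident),
                    aligned_length=int(alen),
                    score=float(score),
                )
            )
    return hits, skipped


def _identity_from_nm(nm: int, match_cols: int, indel_bases: int) -> float:
    """Percent identity over aligned columns, from the SAM NM edit
    distance (NM counts mismatches plus inserted/deleted bases)."""
    if match_cols == 0:
        return 0.0
    mismatches = max(0, nm - indel_bases)
    return 100.0 * (match_cols - mismatches) / match_cols


def _hits_from_sam(path: Path, genome: GenomeIndex | None) -> tuple[list[AlignmentHit], int]:
    hits: list[AlignmentHit] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if genome is not None and chrom not in genome:
                skipped += 1
                continue
            stats = rec.get_cigar_stats()[0]
            match_cols = stats[0] + stats[7] + stats[8]  # M + EQ + X
            indel = stats[1] + stats[2]  # I + D
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0
            hits.append(
                AlignmentHit(
                    read_id=rec.query_name,
                    chromosome=chrom,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    identity=_identity_from_nm(nm, match_cols, indel),
                    aligned_length=match_cols,
                    score=score,
                )
            )
    return hits, skipped


def load_hits(
    path: str | Path,
    dialect: str = "tabular",
    genome: GenomeIndex | None = None,
) -> list[AlignmentHit]:
    """Load alignment hits, normalising coordinates to 0-based
    half-open.

    ``dialect`` is ``tabular`` (the 8-column 1-based format in
    FORMATS.md) or ``sam``.  When a genome index is supplied, hits on
    unknown chromosomes are skipped with a logged warning.
    """
    path = Path(path)
    if dialect == "tabular":
        hits, skipped = _hits_from_tabular(path, genome)
    elif dialect == "sam":
        hits, skipped = _hits_from_sam(path, genome)
    else:
        raise ValueError(f"unknown hit dialect {dialect!r}")
    if skipped:
        logger.warning("%s: skipped %d hits referencing unknown chromosomes", path, skipped)
    return hits


def write_hits_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 1-based inclusive tabular dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.chromosome}\t{h.start + 1}\t{h.end}\t{h.strand}\t"
                f"{h.identity!r}\t{h.aligned_length}\t{h.score!r}\n"
            )


def load_aligned_reads(path: str | Path) -> list[AlignedRead]:
    """Load per-base alignments from a SAM file for variant screening.

    The query sequence and CIGAR must be present; identity is derived
    from the NM tag (100% when absent)."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None or rec.cigartuples is None:
                continue
            cigar = [("MIDNSHP=X"[op], n) for op, n in rec.cigartuples]
            stats = rec.get_cigar_stats()[0]
            match_cols = stats[0] + stats[7] + stats[8]
            indel = stats[1] + stats[2]
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chromosome=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    cigar=cigar,
                    query=rec.query_sequence,
                    identity=_identity_from_nm(nm, match_cols, indel),
                    score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                )
            )
    return reads


# ----------------------------------------------------------------- genes


def load_genes(path: str | Path, fmt: str = "bed") -> list[GeneRecord]:
    """Load gene annotation from BED(6) (0-based half-open) or GFF3
    (1-based inclusive, feature type ``gene``), unified to 0-based
    half-open records."""
    path = Path(path)
    genes: list[GeneRecord] = []
    if fmt == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED needs at least 4 columns")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
                genes.append(GeneRecord(fields[3], chrom, start, end, strand))
    elif fmt == "gff3":
        import gffutils.iterators

        for lineno, feat in enumerate(gffutils.iterators.DataIterator(str(path)), 1):
            if feat.featuretype != "gene":
                continue
            gene_id = (feat.attributes.get("ID") or feat.attributes.get("gene_id") or [None])[0]
            if gene_id is None:
                raise ValueError(f"{path}: gene feature near line {lineno} without ID attribute")
            strand = feat.strand if feat.strand in "+-" else "+"
            # GFF3 is 1-based inclusive
            genes.append(GeneRecord(gene_id, feat.seqid, feat.start - 1, feat.end, strand))
    else:
        raise ValueError(f"unknown gene annotation format {fmt!r}")
    return genes


def write_genes_bed(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# --------------------------------------------------------------- writers


def write_tracks(placements: Iterable[Placement], path: str | Path) -> None:
    """Export placed clones as a BED6 track: the item name carries the
    clone id and placement category, the strand column the insert
    orientation."""
    with open(path, "w") as fh:
        for p in placements:
            if not p.placed:
                continue
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\t{p.clone_id}|{p.category}\t0\t{p.strand}\n"
            )


def _anchor_dip(
    v: VariantCall, ref_seq: str
) -> tuple[int, str, str]:
    """Left-anchor an unanchored DIP for VCF output.

    Returns (1-based POS, REF, ALT).  The anchor base precedes the
    event; an event at position 0 is anchored on the following base
    per VCF convention."""
    if v.position > 0:
        anchor = ref_seq[v.position - 1]
        return v.position, anchor + v.ref_allele, anchor + v.alt_allele
    if v.ref_allele:  # deletion at origin: anchor after the run
        anchor = ref_seq[v.position + len(v.ref_allele)]
        return 1, v.ref_allele + anchor, anchor
    anchor = ref_seq[v.position]
    return 1, anchor, v.alt_allele + anchor


def write_variants(
    variants: Sequence[VariantCall],
    path: str | Path,
    reference: Mapping[str, str],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write calls as VCF 4.2.  SNPs are emitted as-is; DIPs are
    left-anchored and flagged ``CANDIDATE_DIP`` in INFO."""
    contig_lengths = contig_lengths or {c: len(s) for c, s in reference.items()}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read count">\n')
        fh.write(
            '##INFO=<ID=CANDIDATE_DIP,Number=0,Type=Flag,'
            'Description="Candidate deletion/insertion polymorphism; genotyping warranted">\n'
        )
        fh.write('##INFO=<ID=READS,Number=.,Type=String,Description="Supporting read ids">\n')
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if v.vtype == "SNP":
                pos1, ref_a, alt_a = v.position + 1, v.ref_allele, v.alt_allele
                info = f"SUPPORT={v.support_count};READS={','.join(v.read_ids)}"
            else:
                pos1, ref_a, alt_a = _anchor_dip(v, reference[v.chromosome])
                info = f"SUPPORT={v.support_count};CANDIDATE_DIP;READS={','.join(v.read_ids)}"
            fh.write(f"{v.chromosome}\t{pos1}\t.\t{ref_a}\t{alt_a}\t.\tPASS\t{info}\n")


def write_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write a list of homogeneous dict rows as TSV."""
    import pandas as pd

    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)
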