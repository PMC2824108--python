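"""Candidate SNP and DIP screening from end-read alignments.

Reads aligned against the reference are screened column by column:
every mismatch column yields a SNP candidate and every insertion or
deletion run yields one DIP (deletion/insertion polymorphism)
candidate.  Calls with identical position and alleles across reads are
merged, accumulating read support.  DIPs remain candidate variants
pending follow-up genotyping.

A read contributes only when it passes the screening filters:
identity >= 92%, aligned fraction of the read >= 80%, and match
length strictly greater than 250 bp (the first two inclusive, the
last strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import AlignedRead


@dataclass(frozen=True)
class VariantCall:
    """One candidate variant with its supporting reads.

    Alleles are stored unanchored: a SNP has two single differing
    bases; a DIP has exactly one empty allele (``ref_allele`` empty
    for insertions, ``alt_allele`` empty for deletions).  VCF
    left-anchoring is applied only on output.
    """

    chromosome: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    vtype: str  # SNP | DIP
    read_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.vtype == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNP alleles must differ")
        elif self.vtype == "DIP":
            if (self.ref_allele == "") == (self.alt_allele == ""):
                raise ValueError("DIP must have exactly one empty allele")
        else:
            raise ValueError(f"unknown variant type {self.vtype!r}")

    @property
    def support_count(self) -> int:
        return len(self.read_ids)

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele, self.vtype)


def read_passes_variant_filters(
    read: AlignedRead,
    min_identity: float = 92.0,
    min_len_frac: float = 0.80,
    min_match: int = 250,
    min_score: float | None = None,
) -> bool:
    """Screening filter for variant-calling reads.

    ``identity`` and the aligned read fraction are inclusive bounds;
    the match length must strictly exceed ``min_match`` base pairs.  An
    optional alignment-score threshold can be supplied for mappers
    whose score is not in base-pair units.
    """
    if read.identity < min_identity:
        return False
    if read.aligned_fraction < min_len_frac:
        return False
    if not read.match_length > min_match:
        return False
    if min_score is not None and read.score < min_score:
        return False
    return True


def _walk_alignment(read: AlignedRead, ref_seq: str) -> Iterable[tuple[int, str, str]]:
    """Yield raw events (ref position, ref allele, alt allele) from the
    CIGAR walk; SNPs as single-base pairs, DIPs with one empty side."""
    rpos = read.start
    qpos = 0
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                rb = ref_seq[rpos + i].upper()
                qb = read.query[qpos + i].upper()
                if rb != qb:
                    yield rpos + i, rb, qb
            rpos += n
            qpos += n
        elif op == "I":
            yield rpos, "", read.query[qpos : qpos + n].upper()
            qpos += n
        elif op == "D":
            yield rpos, ref_seq[rpos : rpos + n].upper(), ""
            rpos += n
        elif op in "SH":
            if op == "S":
                qpos += n
        elif op == "N":
            rpos += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r} in read {read.read_id!r}")


def call_variants(
    reads: Sequence[AlignedRead],
    reference: Mapping[str, str],
    min_identity: float = 92.0,
    min_len_frac: float = 0.80,
    min_match: int = 250,
    min_score: float | None = None,
) -> list[VariantCall]:
    """Call candidate SNPs and DIPs from aligned reads.

    Reads failing the screening filters emit nothing.  Identical calls
    across reads are merged with their supporting read ids pooled.
    Output is sorted by (chromosome, position, type, alleles) and is
    invariant under read input order.
    """
    by_key: dict[tuple, list[str]] = {}
    for read in sorted(reads, key=lambda r: r.read_id):
        if not read_passes_variant_filters(
            read, min_identity, min_len_frac, min_match, min_score
        ):
            continue
        if read.chromosome not in reference:
            raise ValueError(f"read {read.read_id!r} aligned to unknown chromosome")
        ref_seq = reference[read.chromosome]
        if read.end > len(ref_seq):
            raise ValueError(
                f"read {read.read_id!r} alignment runs past the end of "
                f"{read.chromosome} ({read.end} > {len(ref_seq)}): corrupt alignment"
            )
        for pos, ref_a, alt_a in _walk_alignment(read, ref_seq):
            vtype = "SNP" if ref_a and alt_a else "DIP"
            key = (read.chromosome, pos, ref_a, alt_a, vtype)
            by_key.setdefault(key, []).append(read.read_id)
    calls = [
        VariantCall(chrom, pos, ref_a, alt_a, vtype, tuple(rids))
        for (chrom, pos, ref_a, alt_a, vtype), rids in by_key.items()
    ]
    calls.sort(key=lambda c: (c.chromosome, c.position, c.vtype, c.ref_allele, c.alt_allele))
    return calls
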