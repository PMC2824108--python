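"""Core domain types shared by every stage of the pipeline.

All genomic intervals are stored 0-based half-open; conversion from
1-based inclusive conventions (tabular hits, GFF3, SAM, VCF) happens
only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


CHROM_CLASSES = ("autosome", "X", "Y", "other")


def default_chrom_class(name: str) -> str:
    """Classify a chromosome by name: ``X``/``Y`` (with or without a
    ``chr`` prefix) map to the sex-chromosome classes, anything else is
    an autosome."""
    base = name[3:] if name.lower().startswith("chr") else name
    if base.upper() == "X":
        return "X"
    if base.upper() == "Y":
        return "Y"
    return "autosome"


@dataclass(frozen=True)
class ChromEntry:
    name: str
    length: int
    chrom_class: str = "autosome"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} has non-positive length {self.length}")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"unknown chromosome class {self.chrom_class!r}")


class GenomeIndex:
    """Ordered set of chromosome names and lengths defining the
    coordinate space.

    Order is preserved for reporting; names must be unique and lengths
    positive.
    """

    def __init__(self, entries: Iterable[ChromEntry]):
        self.entries: list[ChromEntry] = list(entries)
        self._by_name: dict[str, ChromEntry] = {}
        for e in self.entries:
            if e.name in self._by_name:
                raise ValueError(f"duplicate chromosome name {e.name!r}")
            self._by_name[e.name] = e

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int], classify=default_chrom_class) -> "GenomeIndex":
        return cls(ChromEntry(n, l, classify(n)) for n, l in lengths.items())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[ChromEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self.entries == other.entries

    def __getitem__(self, name: str) -> ChromEntry:
        return self._by_name[name]

    def length(self, name: str) -> int:
        return self._by_name[name].length

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def total_length(self, chrom_class: str | None = None) -> int:
        return sum(
            e.length for e in self.entries if chrom_class is None or e.chrom_class == chrom_class
        )


@dataclass(frozen=True)
class EndRead:
    """One end-sequence read of a BAC clone (e.g. from the T7 or SP6
    vector primer)."""

    read_id: str
    clone_id: str
    end_label: str
    read_length: int
    passed_qc: bool = True

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"read {self.read_id!r}: read_length must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate mapping of one end read.

    ``identity`` is the percent of aligned columns that match the
    reference; ``aligned_length`` the number of aligned bases.
    """

    read_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    identity: float
    aligned_length: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"hit for {self.read_id!r}: start must be < end")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"hit for {self.read_id!r}: identity outside [0, 100]")
        if self.strand not in "+-":
            raise ValueError(f"hit for {self.read_id!r}: strand must be '+' or '-'")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: start must be < end")


# CIGAR operations that consume read / reference bases, SAM semantics.
_CONSUMES_READ = set("MIS=X")
_CONSUMES_REF = set("MDN=X")


@dataclass
class AlignedRead:
    """A read alignment carrying enough per-column information to
    reconstruct read-vs-reference columns: CIGAR run lengths plus the
    read bases themselves.

    ``match_length`` counts aligned (M/=/X) columns, ``identity`` the
    percent of those columns that match the reference.
    """

    read_id: str
    chromosome: str
    start: int
    strand: str
    cigar: list[tuple[str, int]]
    query: str
    identity: float = 100.0
    read_length: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length == 0:
            self.read_length = len(self.query)
        qlen = sum(n for op, n in self.cigar if op in _CONSUMES_READ)
        if qlen != len(self.query):
            raise ValueError(
                f"read {self.read_id!r}: CIGAR consumes {qlen} read bases "
                f"but query is {len(self.query)} bp"
            )

    @property
    def match_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "M=X")

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    @property
    def end(self) -> int:
        return self.start + self.reference_span

    @property
    def aligned_fraction(self) -> float:
        return self.match_length / self.read_length if self.read_length else 0.0


def cigar_from_string(text: str) -> list[tuple[str, int]]:
    """Parse a SAM CIGAR string into (op, length) runs."""
    runs: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MIDNSHP=X":
                raise ValueError(f"malformed CIGAR {text!r}")
            runs.append((ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {text!r}")
    return runs


def cigar_to_string(runs: Iterable[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in runs)
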