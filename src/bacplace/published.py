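"""Published end-sequencing statistics for the two NOD mouse BAC
libraries (DIL NOD, ~150 kb inserts; CHORI-29, ~205 kb inserts),
mapped against the NCBIm37 C57BL/6J reference assembly.

The packaged tables carry only the *integer* columns of the published
per-chromosome coverage tables and library summaries; every derived
quantity (clone depth, % coverage, aggregate depths, percentages,
placed-clone totals) is recomputed from them by the coverage and
placement modules, so the toolkit's arithmetic can be checked against
the printed reports.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coverage import CoverageRow, aggregate_rows
from .model import ChromEntry, GenomeIndex, default_chrom_class
from .placement import LibrarySummary

LIBRARIES = ("dil_nod", "chori29")


def _data_path(name: str):
    return resources.files("bacplace").joinpath("data", name)


def load_coverage_inputs(library: str) -> pd.DataFrame:
    """Integer per-chromosome coverage columns for ``dil_nod`` or
    ``chori29``."""
    if library not in LIBRARIES:
        raise ValueError(f"unknown library {library!r}")
    with resources.as_file(_data_path(f"{library}_coverage.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chromosome": str})


def coverage_rows(library: str) -> list[CoverageRow]:
    """Published per-chromosome rows with derived columns recomputed,
    followed by autosome/X/Y, genome and genome-excluding-Y
    aggregates."""
    df = load_coverage_inputs(library)
    rows = [
        CoverageRow(
            chromosome=r.chromosome,
            total_chr_length=int(r.total_chr_length),
            nonredundant_clone_length=int(r.nonredundant_clone_length),
            clone_length_total=int(r.clone_length_total),
            passed_aligned_sequence=int(r.passed_aligned_sequence),
        )
        for r in df.itertuples()
    ]
    genome = GenomeIndex(
        ChromEntry(r.chromosome, r.total_chr_length, default_chrom_class(r.chromosome))
        for r in rows
    )
    return rows + aggregate_rows(rows, genome)


def library_summary(library: str) -> LibrarySummary:
    """Published sequencing-and-alignment summary counts, from which
    the derived percentages and the placed-uniquely total are
    recomputed."""
    if library not in LIBRARIES:
        raise ValueError(f"unknown library {library!r}")
    with resources.as_file(_data_path(f"{library}_summary.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    counts = dict(zip(df["field"], df["count"].astype(int)))
    return LibrarySummary(**counts)
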