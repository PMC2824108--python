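"""Clone placement from end-read alignment hits.

A BAC clone is placed on the genome when its two end reads align in a
configuration compatible with a single insert: same chromosome,
opposite strands, facing inward, and spanning a distance consistent
with the library's insert-size distribution.  The insert-size
distribution itself is estimated iteratively from both-ends-unique
clones, rejecting spans more than ``sd_window`` (default 3) standard
deviations from the mean after each round.

Categories assigned to every clone:

``unique_pair``
    both ends aligned uniquely and form a consistent pair.
``rescued``
    one end unique; exactly one of the mate's multiple hits is
    consistent with it.
``ambiguous``
    more than one consistent configuration exists.
``single_end``
    one end unique but no consistent mate hit.
``same_strand_rejected``
    both ends unique but orientation-incompatible (same strand, or
    opposite strands facing outward).
``distance_rejected``
    both ends unique but on different chromosomes or at an
    unrealistic distance (span outside mean +/- sd_window * sd).
``unplaced``
    nothing aligned, or no configuration is consistent.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import AlignmentHit, EndRead

PLACED_CATEGORIES = ("unique_pair", "rescued")
ALL_CATEGORIES = (
    "unique_pair",
    "rescued",
    "ambiguous",
    "single_end",
    "same_strand_rejected",
    "distance_rejected",
    "unplaced",
)

DEFAULT_CLONE_REGEX = r"^(?P<clone>.+)\.(?P<end>[^.]+)$"


def parse_read_id(read_id: str, pattern: str = DEFAULT_CLONE_REGEX) -> tuple[str, str]:
    """Split a read identifier into (clone_id, end_label).

    The default convention is ``<cloneID>.<endlabel>``, e.g.
    ``bQ123A1.T7``; the grammar is configurable because clone naming
    schemes are library-specific.
    """
    m = re.match(pattern, read_id)
    if not m:
        raise ValueError(f"read id {read_id!r} does not match clone pattern {pattern!r}")
    return m.group("clone"), m.group("end")


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_span: int = 100,
    min_identity: float = 95.0,
) -> list[AlignmentHit]:
    """Keep hits where *more than* ``min_span`` bases align with
    *greater than* ``min_identity`` percent identity.

    Both thresholds are strict inequalities: a hit of exactly 100
    aligned bases, or exactly 95% identity, is rejected.
    """
    return [
        h for h in hits if h.aligned_length > min_span and h.identity > min_identity
    ]


def hits_by_read(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    out: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        out[h.read_id].append(h)
    return dict(out)


def classify_read_uniqueness(read_hits: Sequence[AlignmentHit]) -> str:
    """``unique`` iff exactly one filtered hit exists, ``multiple`` for
    more than one, ``unaligned`` for none."""
    n = len(read_hits)
    if n == 0:
        return "unaligned"
    return "unique" if n == 1 else "multiple"


@dataclass
class CloneEnds:
    """A clone with its (up to) two end reads and their filtered hits."""

    clone_id: str
    reads: dict[str, EndRead] = field(default_factory=dict)  # end_label -> read
    hits: dict[str, list[AlignmentHit]] = field(default_factory=dict)  # end_label -> hits

    def end_labels(self) -> list[str]:
        return sorted(self.reads)

    def uniqueness(self, end_label: str) -> str:
        return classify_read_uniqueness(self.hits.get(end_label, []))


def group_clones(
    reads: Iterable[EndRead],
    filtered_hits: Iterable[AlignmentHit],
) -> list[CloneEnds]:
    """Group end reads and their hits by clone, preserving read order."""
    clones: dict[str, CloneEnds] = {}
    by_read = hits_by_read(filtered_hits)
    for r in reads:
        c = clones.setdefault(r.clone_id, CloneEnds(r.clone_id))
        if r.end_label in c.reads:
            raise ValueError(f"clone {r.clone_id!r} has two reads labelled {r.end_label!r}")
        c.reads[r.end_label] = r
        c.hits[r.end_label] = by_read.get(r.read_id, [])
    return list(clones.values())


def _pair_geometry(a: AlignmentHit, b: AlignmentHit) -> tuple[str, int]:
    """Classify the geometry of two hits of a pair.

    Returns (status, span) where status is one of ``ok`` (same
    chromosome, opposite strands, inward facing), ``orientation``
    (same strand or outward facing) or ``chromosome``.  Span is the
    outermost distance (0 when undefined).
    """
    if a.chromosome != b.chromosome:
        return "chromosome", 0
    if a.strand == b.strand:
        return "orientation", 0
    fwd, rev = (a, b) if a.strand == "+" else (b, a)
    # Inward: the forward read points right and lies left of the
    # reverse read; outward pairs cannot bound one insert.
    if fwd.start > rev.start:
        return "orientation", 0
    return "ok", max(a.end, b.end) - min(a.start, b.start)


@dataclass(frozen=True)
class InsertStats:
    """Insert-size distribution of a library, with the acceptance
    window used for placement."""

    mean: float
    sd: float
    n_used: int
    n_rejected: int
    iterations: int
    sd_window: float = 3.0

    @property
    def lower(self) -> float:
        return self.mean - self.sd_window * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.sd_window * self.sd

    def accepts(self, span: float) -> bool:
        return self.lower <= span <= self.upper

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "n_used": self.n_used,
            "n_rejected": self.n_rejected,
            "iterations": self.iterations,
            "sd_window": self.sd_window,
            "lower": self.lower,
            "upper": self.upper,
        }


def candidate_spans(clones: Iterable[CloneEnds]) -> list[int]:
    """Spans of clones usable for insert-size estimation: both ends
    unique, same chromosome, opposite strands, inward facing.  No span
    cut is applied here; outliers are rejected inside the iteration."""
    spans = []
    for c in clones:
        labels = c.end_labels()
        if len(labels) != 2:
            continue
        if any(c.uniqueness(l) != "unique" for l in labels):
            continue
        a, b = (c.hits[l][0] for l in labels)
        status, span = _pair_geometry(a, b)
        if status == "ok":
            spans.append(span)
    return spans


def estimate_insert_stats(
    spans: Sequence[float],
    sd_window: float = 3.0,
    max_iter: int = 20,
    tol: float = 0.5,
) -> InsertStats:
    """Iteratively estimate the insert-size mean and SD with outlier
    rejection.

    Each round computes the mean and standard deviation (n-1
    denominator) of the currently accepted spans and rejects spans more
    than ``sd_window`` standard deviations from the mean.  Iteration
    stops when a round rejects nothing, the mean moves by less than
    ``tol`` base pairs, or ``max_iter`` rounds have run.  Rejected
    spans are never re-admitted.
    """
    accepted = [float(s) for s in spans]
    if len(accepted) < 2:
        raise ValueError(
            f"insert-size estimation needs at least 2 usable both-ends-unique "
            f"pairs, got {len(accepted)}"
        )
    prev_mean = math.inf
    mean = sd = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        n = len(accepted)
        mean = sum(accepted) / n
        var = sum((s - mean) ** 2 for s in accepted) / (n - 1) if n > 1 else 0.0
        sd = math.sqrt(var)
        lo, hi = mean - sd_window * sd, mean + sd_window * sd
        kept = [s for s in accepted if lo <= s <= hi]
        if len(kept) < 2:
            raise ValueError(
                "insert-size estimation degenerated to fewer than 2 spans; "
                "check the hit filters and library configuration"
            )
        no_rejection = len(kept) == len(accepted)
        converged = abs(mean - prev_mean) < tol
        accepted = kept
        prev_mean = mean
        if no_rejection or converged:
            break
    return InsertStats(
        mean=mean,
        sd=sd,
        n_used=len(accepted),
        n_rejected=len(spans) - len(accepted),
        iterations=iterations,
        sd_window=sd_window,
    )


@dataclass(frozen=True)
class Placement:
    """One clone's resolved genomic interval and provenance category.

    For placed categories (``unique_pair``, ``rescued``) the interval
    is the outermost span of the two end-read hits and ``orientation``
    records which end label is leftmost.
    """

    clone_id: str
    category: str
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None
    orientation: str | None = None
    hit_refs: tuple[str, ...] = ()

    @property
    def placed(self) -> bool:
        return self.category in PLACED_CATEGORIES

    @property
    def span(self) -> int:
        if self.start is None or self.end is None:
            return 0
        return self.end - self.start

    @property
    def strand(self) -> str:
        """Insert orientation for track export: '+' when the
        forward-strand read is the leftmost end."""
        return "+" if self.orientation == "fwd_left" else "-"


def _make_placement(
    clone: CloneEnds,
    category: str,
    a: AlignmentHit | None = None,
    b: AlignmentHit | None = None,
) -> Placement:
    if a is None or b is None:
        return Placement(clone.clone_id, category)
    fwd = a if a.strand == "+" else b
    return Placement(
        clone_id=clone.clone_id,
        category=category,
        chromosome=a.chromosome,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        orientation="fwd_left" if fwd.start == min(a.start, b.start) else "fwd_right",
        hit_refs=(a.read_id, b.read_id),
    )


def place_unique_pairs(clone: CloneEnds, stats: InsertStats) -> Placement:
    """Classify a both-ends-unique clone.

    Same chromosome + opposite strands + inward + span within the
    stats window -> ``unique_pair``; orientation failures ->
    ``same_strand_rejected``; different chromosomes or span outside
    the window -> ``distance_rejected``.
    """
    la, lb = clone.end_labels()
    a, b = clone.hits[la][0], clone.hits[lb][0]
    status, span = _pair_geometry(a, b)
    if status == "chromosome":
        return _make_placement(clone, "distance_rejected")
    if status == "orientation":
        return _make_placement(clone, "same_strand_rejected")
    if not stats.accepts(span):
        return _make_placement(clone, "distance_rejected")
    return _make_placement(clone, "unique_pair", a, b)


def _consistent_mate_hits(
    anchor: AlignmentHit, mate_hits: Sequence[AlignmentHit], stats: InsertStats
) -> list[AlignmentHit]:
    out = []
    for h in mate_hits:
        status, span = _pair_geometry(anchor, h)
        if status == "ok" and stats.accepts(span):
            out.append(h)
    return out


def rescue_single_unique(clone: CloneEnds, stats: InsertStats) -> Placement:
    """Classify a clone with one unique end and a multiply-mapped mate.

    Among the mate's hits, those on the unique end's chromosome, on the
    opposite strand, inward facing and with an implied span inside the
    stats window are candidates.  Exactly one candidate -> ``rescued``;
    none -> ``single_end``; two or more -> ``ambiguous``.  No
    best-score fallback is applied: the position must be definitive.
    """
    labels = clone.end_labels()
    uniq_label = next(l for l in labels if clone.uniqueness(l) == "unique")
    mate_label = next(l for l in labels if l != uniq_label)
    anchor = clone.hits[uniq_label][0]
    candidates = _consistent_mate_hits(anchor, clone.hits[mate_label], stats)
    if len(candidates) == 1:
        return _make_placement(clone, "rescued", anchor, candidates[0])
    if len(candidates) == 0:
        return _make_placement(clone, "single_end")
    return _make_placement(clone, "ambiguous")


def _place_both_multiple(clone: CloneEnds, stats: InsertStats) -> Placement:
    # Clones whose both ends map multiply are never rescued; they are
    # ambiguous when some hit pair could form a consistent clone,
    # otherwise unplaced.
    la, lb = clone.end_labels()
    for a in clone.hits[la]:
        if _consistent_mate_hits(a, clone.hits[lb], stats):
            return _make_placement(clone, "ambiguous")
    return _make_placement(clone, "unplaced")


def place_clone(clone: CloneEnds, stats: InsertStats) -> Placement:
    """Assign exactly one category to a clone from its end uniqueness."""
    labels = clone.end_labels()
    kinds = sorted(clone.uniqueness(l) for l in labels)
    if len(labels) < 2:
        if kinds == ["unique"]:
            return _make_placement(clone, "single_end")
        return _make_placement(clone, "unplaced")
    if kinds == ["unique", "unique"]:
        return place_unique_pairs(clone, stats)
    if kinds == ["multiple", "unique"]:
        return rescue_single_unique(clone, stats)
    if kinds == ["unaligned", "unique"]:
        return _make_placement(clone, "single_end")
    if kinds == ["multiple", "multiple"]:
        return _place_both_multiple(clone, stats)
    return _make_placement(clone, "unplaced")


def place_clones(clones: Iterable[CloneEnds], stats: InsertStats) -> list[Placement]:
    return [place_clone(c, stats) for c in clones]


@dataclass(frozen=True)
class LibrarySummary:
    """Sequencing-and-alignment summary of one library, the shape of a
    clone-resource report table."""

    clones_in_library: int
    attempted_reads: int
    reads_passed: int
    clones_both_ends_passed: int
    reads_aligned: int
    reads_unique: int
    reads_multiple: int
    clones_unique_pairs: int
    clones_rescued: int

    def __post_init__(self) -> None:
        if self.reads_unique + self.reads_multiple != self.reads_aligned:
            raise ValueError(
                "inconsistent summary: unique + multiple reads must equal aligned reads"
            )

    @property
    def clones_placed_uniquely(self) -> int:
        return self.clones_unique_pairs + self.clones_rescued

    @property
    def pct_reads_aligned(self) -> float:
        """Passed reads with an alignment, as a printed percentage."""
        from .util import round_half_up

        if self.reads_passed == 0:
            return 0.0
        return round_half_up(100.0 * self.reads_aligned / self.reads_passed, 1)

    @property
    def pct_reads_unique(self) -> float:
        """Aligned reads with a single definitive location, as a
        printed percentage."""
        from .util import round_half_up

        if self.reads_aligned == 0:
            return 0.0
        return round_half_up(100.0 * self.reads_unique / self.reads_aligned, 1)

    def to_dict(self) -> dict:
        return {
            "clones_in_library": self.clones_in_library,
            "attempted_reads": self.attempted_reads,
            "reads_passed": self.reads_passed,
            "clones_both_ends_passed": self.clones_both_ends_passed,
            "reads_aligned": self.reads_aligned,
            "reads_unique": self.reads_unique,
            "reads_multiple": self.reads_multiple,
            "clones_unique_pairs": self.clones_unique_pairs,
            "clones_rescued": self.clones_rescued,
            "clones_placed_uniquely": self.clones_placed_uniquely,
            "pct_reads_aligned": self.pct_reads_aligned,
            "pct_reads_unique": self.pct_reads_unique,
        }


def summarize_library(
    reads: Sequence[EndRead],
    filtered_hits: Iterable[AlignmentHit],
    placements: Sequence[Placement],
    clones_in_library: int | None = None,
    attempted_reads: int | None = None,
) -> LibrarySummary:
    """Build the library summary from reads, filtered hits and
    placements.

    Uniqueness is counted before the insert-size iterations, i.e. on
    the filtered hit sets as loaded.  ``clones_in_library`` and
    ``attempted_reads`` default to what the inputs contain but can be
    overridden when the library is larger than the sequenced subset.
    """
    passed = [r for r in reads if r.passed_qc]
    by_read = hits_by_read(filtered_hits)
    passed_ids = {r.read_id for r in passed}
    n_unique = n_multiple = 0
    for rid in passed_ids:
        kind = classify_read_uniqueness(by_read.get(rid, []))
        if kind == "unique":
            n_unique += 1
        elif kind == "multiple":
            n_multiple += 1
    per_clone: dict[str, int] = defaultdict(int)
    for r in passed:
        per_clone[r.clone_id] += 1
    counts = {cat: 0 for cat in ALL_CATEGORIES}
    for p in placements:
        counts[p.category] += 1
    return LibrarySummary(
        clones_in_library=(
            clones_in_library if clones_in_library is not None else len({r.clone_id for r in reads})
        ),
        attempted_reads=attempted_reads if attempted_reads is not None else len(reads),
        reads_passed=len(passed),
        clones_both_ends_passed=sum(1 for n in per_clone.values() if n >= 2),
        reads_aligned=n_unique + n_multiple,
        reads_unique=n_unique,
        reads_multiple=n_multiple,
        clones_unique_pairs=counts["unique_pair"],
        clones_rescued=counts["rescued"],
    )


def category_counts(placements: Iterable[Placement]) -> dict[str, int]:
    counts = {cat: 0 for cat in ALL_CATEGORIES}
    for p in placements:
        counts[p.category] += 1
    return counts
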