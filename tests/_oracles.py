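"""Independent brute-force oracles used to cross-check the library.

These deliberately re-derive each quantity from first principles with
plain loops (per-base boolean arrays, all-pairs scans, exhaustive hit
enumeration) and share no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def footprint_boolarray(intervals, axis_length: int) -> int:
    """Bases covered at least once, via a per-base boolean array."""
    mask = np.zeros(axis_length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def filter_hits_loop(hits, min_span, min_identity):
    kept = []
    for h in hits:
        if h.aligned_length > min_span and h.identity > min_identity:
            kept.append(h)
    return kept


def iterative_rejection_loop(spans, sd_window=3.0, max_iter=20, tol=0.5):
    """Mean/SD with 3-SD rejection, re-derived as an explicit loop.

    Returns (mean, sd, rejected_spans).
    """
    current = [float(s) for s in spans]
    rejected = []
    prev_mean = None
    for _ in range(max_iter):
        n = len(current)
        mean = sum(current) / n
        sd = (sum((x - mean) ** 2 for x in current) / (n - 1)) ** 0.5 if n > 1 else 0.0
        keep, drop = [], []
        for x in current:
            if mean - sd_window * sd <= x <= mean + sd_window * sd:
                keep.append(x)
            else:
                drop.append(x)
        rejected.extend(drop)
        stop = not drop or (prev_mean is not None and abs(mean - prev_mean) < tol)
        prev_mean = mean
        current = keep
        if stop:
            break
    return mean, sd, rejected


def _pair_ok(a, b, lower, upper):
    if a.chromosome != b.chromosome or a.strand == b.strand:
        return False
    fwd, rev = (a, b) if a.strand == "+" else (b, a)
    if fwd.start > rev.start:
        return False
    span = max(a.end, b.end) - min(a.start, b.start)
    return lower <= span <= upper


def enumerate_clone_category(hits_by_end: dict, lower: float, upper: float) -> str:
    """Exhaustively enumerate all hit pairs of a clone and classify it
    from the category definitions."""
    labels = sorted(hits_by_end)
    if len(labels) < 2:
        n = len(hits_by_end[labels[0]]) if labels else 0
        return "single_end" if n == 1 else "unplaced"
    ha, hb = hits_by_end[labels[0]], hits_by_end[labels[1]]
    na, nb = len(ha), len(hb)
    if na == 1 and nb == 1:
        a, b = ha[0], hb[0]
        if a.chromosome != b.chromosome:
            return "distance_rejected"
        if _pair_ok(a, b, lower, upper):
            return "unique_pair"
        if a.strand == b.strand:
            return "same_strand_rejected"
        fwd, rev = (a, b) if a.strand == "+" else (b, a)
        if fwd.start > rev.start:
            return "same_strand_rejected"  # outward-facing
        return "distance_rejected"
    if (na == 1) != (nb == 1) and min(na, nb) >= 1:
        anchor = ha[0] if na == 1 else hb[0]
        mates = hb if na == 1 else ha
        n_ok = sum(1 for m in mates if _pair_ok(anchor, m, lower, upper))
        if n_ok == 1:
            return "rescued"
        return "single_end" if n_ok == 0 else "ambiguous"
    if na == 1 and nb == 0 or na == 0 and nb == 1:
        return "single_end"
    if na >= 2 and nb >= 2:
        for a in ha:
            for b in hb:
                if _pair_ok(a, b, lower, upper):
                    return "ambiguous"
        return "unplaced"
    return "unplaced"


def gene_status_allpairs(gene, clone_intervals) -> str:
    """All-pairs containment/overlap scan for one gene."""
    overlaps = contains = False
    for chrom, s, e in clone_intervals:
        if chrom != gene.chromosome:
            continue
        if s < gene.end and gene.start < e:
            overlaps = True
        if s <= gene.start and gene.end <= e:
            contains = True
    if contains:
        return "full"
    return "partial" if overlaps else "gap"
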