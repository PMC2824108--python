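# Methods

## The placement model

A BAC clone is an (unobserved) contiguous genomic insert of roughly
100–300 kb whose two extremities are Sanger-sequenced from vector
primers. If both end reads align to the reference, the clone's
position is the outermost span of the two alignments, and the pair is
believable only when it is geometrically consistent with one insert:
same chromosome, reads on opposite strands *facing inward* (the
forward-strand read leftmost), and a span compatible with the
library's insert-size distribution. Opposite-strand pairs facing
outward cannot bound an insert and are treated as orientation
failures alongside same-strand pairs (the `same_strand_rejected`
category covers both).

"Compatible with the distribution" is operationalized as the span
lying within mean ± `sd_window`·SD (default 3) of the iteratively
estimated insert-size distribution; this is the only distance rule
applied, to both pair placement and mate rescue.

### Insert-size estimation

The estimation set is every both-ends-unique, same-chromosome,
opposite-strand, inward-facing pair, with no prior span cut — the
first outlier rejection happens inside iteration 1. Each round
recomputes mean and SD (n−1 denominator) over the currently accepted
spans and drops spans outside the 3-SD window; rejected spans are
never re-admitted. Iteration stops when a round rejects nothing, the
mean moves by less than `tol` (default 0.5 bp — effectively "no
change" at base-pair resolution), or `max_iter` = 20 rounds have run.
The procedure is deterministic given the input: rejection is
threshold-based, not sampling-based. Fewer than two usable pairs is a
hard error; a degenerate all-equal set yields SD 0 and a one-point
acceptance window, which is correct for such a library.

### Mate rescue

A clone with one unique end and one multiply-mapped end is placed
when **exactly one** of the mate's filtered hits satisfies all pair
constraints against the unique anchor. No best-score fallback is
applied: with two or more satisfying hits the clone is `ambiguous`,
with none it is `single_end`. The position must be definitive, not
merely favoured. Clones whose ends both map multiply are never
rescued; they are `ambiguous` when some hit pair could satisfy the
constraints and `unplaced` otherwise. Sub-threshold mate hits
(rejected by the alignment filters) are not considered rescue
candidates.

### Filters and boundaries

Mapping filter: aligned length **> 100 bp** and identity **> 95%**,
both strict. Variant-screen filter: identity **≥ 92%**, aligned
fraction of the read **≥ 80%**, match length **> 250 bp** — the first
two inclusive, the last strict. The differing strictness follows the
wording of the thresholds the screen reproduces; a constructed test
fixes each boundary. The variant screen's "match score or match
length" criterion is implemented as match length in base pairs, with
an optional separate score threshold, since a bp unit is meaningful
only for a length. Read uniqueness in the library summary is counted
on the filtered hit sets as loaded, i.e. before the insert-size
iterations.

## Coverage statistics

Only placed clones (`unique_pair`, `rescued`) contribute. Per
chromosome: *clone-length total* = Σ spans (overlaps counted
multiply), *non-redundant clone length* = merged-union footprint,
*clone depth* = clone-length total / chromosome length, *% coverage*
= 100 · non-redundant / chromosome length. *Passed aligned sequence*
is the sum of aligned end-read lengths of placed clones, not clone
spans. Chromosome rows are printed half-up at 2 decimals; aggregate
rows (per chromosome class, genome-wide, and genome-wide excluding Y,
since a female-donor library leaves Y empty) at 1 decimal. Raw
integers and full-precision ratios are kept alongside the printed
values so downstream arithmetic never happens on rounded numbers.
Genome-wide aggregates are reported both with and without chromosome
Y; recomputation of the published tables shows their genome-wide
percentages use the all-chromosome denominator.

Gene coverage: *full* requires containment within a **single** clone
(switchable to union-containment via
`full_requires_single_clone=False`), *gap* means no clone intersects
the gene, *partial* is everything between. Cross-library
intersections (partial-in-both, absent-in-both) are computed over the
shared gene set.

## Variant screen

Qualifying reads are walked column by column against the reference
(CIGAR plus query sequence): each mismatch column emits a SNP, each
insertion/deletion run one DIP, stored unanchored internally and
left-anchored only at VCF output. Identical calls across reads merge
with pooled read support. Single-read support suffices — the
neighbourhood-quality and double-strand confirmation heuristics of
trace-level SNP callers are not modelled — so DIPs are flagged
`CANDIDATE_DIP` and `SUPPORT` is reported for downstream filtering.
Calls are sorted and invariant under read input order.

## The simulator

`SimConfig` defaults are the study conditions of a ~150 kb library:
insert mean 150,000 bp with SD 15,000 (10% — the published
distribution's spread is not stated numerically; 10% reproduces its
visual width), read lengths Normal(694, 30²) bp, 3% insertless
clones, post-QC sequencing error 10⁻³/base, strain-divergence rates
of 8·10⁻⁴ SNPs and 7·10⁻⁵ DIPs per base (the ratio of the published
variant totals to total sequence generated). The
`large_insert_preset` switches to a 205 kb / 1%-insertless,
male-donor library with the X chromosome sampled at half weight.
Chromosomes are desk-scale (2 + 1.5 + 1 Mb, last one "X") so the full
pipeline runs in seconds; 500 clones give ~16-fold depth, enough for
all coverage and estimation statistics.

Multi-mapping is induced *structurally*: repeat families (default 8
families × 3 identical 20 kb copies, ~11% of the genome) are pasted
into the reference, and a read whose interval lies wholly inside a
copy genuinely aligns to every copy. This exercises mate rescue
against real ambiguity instead of fabricated extra hits. Real
mammalian genomes are far more repetitive (roughly half of real
end reads multi-map); the default keeps the both-ends-unique
estimation set large enough that insert-mean recovery stays
well-conditioned at 500 clones. Each clone draws from its own seeded
substream, so enlarging a library extends rather than reshuffles it;
all outputs are byte-deterministic in the seed.

What the simulator does **not** emulate: base-quality profiles and
chromatograms, non-uniform cloning bias (EcoRI site density),
segmental duplications with diverged copies, reference assembly gaps,
and contamination. Passing tests therefore demonstrate the
*correctness of the computations* under known ground truth, not the
field performance of the thresholds on archived trace data.

## Published-table reproduction

The packaged data files carry only the printed *integer* columns of
the published per-chromosome coverage tables and library summaries
for the two NOD libraries; every derived cell (depths, percentages,
placed totals) is recomputed. Round-half-up at the printed precision
reproduces the 150 kb-library table exactly and all percentage
columns of both tables. Two printed cells are internally inconsistent
with their own printed inputs and cannot be reproduced by any
rounding rule: the larger-insert library's chr Y depth (printed 0.62;
the printed quotient is 0.6139) and the 150 kb library's
placed-uniquely total (printed 125,266; its printed components sum to
125,264). The toolkit reports the arithmetically consistent values;
the acceptance tests assert the printed cells and document the
discrepancy by failing.

## Numerical and design choices

* Coordinates are 0-based half-open internally; conversion happens
  only at I/O boundaries (tabular hits, GFF3, SAM, VCF are 1-based).
* Rounding of presentation values is decimal half-up, not float
  `round`, to match how report tables are conventionally printed.
* Clone/end linkage is parsed from read ids by a configurable regex
  (default `<cloneID>.<endlabel>`), since naming grammars are
  library-specific.
* Touching intervals merge ([0,5) ∪ [5,9) → [0,9)): physical
  coverage has no zero-length gaps.
* When the pipeline reconstructs read metadata from hit files alone,
  reads with no alignment record (e.g. insertless clones' reads) are
  invisible to it; supply read metadata separately where those counts
  matter. Read length is then proxied by the read's longest
  alignment.
* SAM identity derives from the `NM` tag with inserted/deleted bases
  subtracted before counting mismatches; absent `NM` means identity
  100%.

## Problem sizes

Test and acceptance runs use 150–500 clones on 4.5 Mb genomes
(seconds per stage), 200 clones on a 100 kb genome for exhaustive
brute-force comparison, and 10 kb axes for per-base coverage oracles
— sizes at which every result can be cross-checked against
independent enumeration.
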