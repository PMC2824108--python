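# File formats

Internal coordinates are 0-based half-open everywhere. The table below
lists each external format, its on-disk coordinate convention, and the
conversion applied at load time.

## Genome index

Either FASTA (lengths counted from the records) or a two-column
whitespace-separated table:

    <chromosome-name> <length-bp>

Blank lines and `#` comments are ignored. Chromosome classes
(autosome / X / Y / other) are assigned from the name: `X`/`chrX` → X,
`Y`/`chrY` → Y, anything else autosome; a custom classifier can be
passed to `load_genome`.

## Tabular hit dialect (`hits.tsv`)

Tab-separated, one candidate alignment per line, **1-based inclusive**
coordinates (converted to 0-based half-open on load):

| column | type | meaning |
|---|---|---|
| read_id | text | end-read identifier (`<cloneID>.<endlabel>` by default) |
| chromosome | text | target sequence name |
| start | int | 1-based first aligned reference base |
| end | int | 1-based last aligned reference base |
| strand | `+`/`-` | alignment strand |
| identity | float | % of aligned columns matching the reference |
| aligned_length | int | number of aligned columns (bp) |
| score | float | mapper score |

`#`-prefixed lines are comments. A row `start=101, end=200` loads as
the interval `(100, 200)`, span 100 bp.

## SAM hit dialect

Standard SAM mandatory fields; plain text. `aligned_length` is the
number of M/=/X columns from the CIGAR; identity is derived from the
`NM` tag (edit distance; insertions/deletions are subtracted before
computing mismatches), 100% when `NM` is absent; score from `AS` when
present. The same file doubles as the per-base alignment input of the
variant screen, which additionally requires the SEQ column.

## Gene annotation

* BED (≥4 columns, 0-based half-open): chrom, start, end, name,
  [score, strand].
* GFF3 (1-based inclusive): only features of type `gene` are read;
  the gene id comes from the `ID` (or `gene_id`) attribute.

## Outputs

* `placements.bed` — BED6; name = `<cloneID>|<category>`; strand
  column = insert orientation (`+` when the forward-strand read is the
  leftmost end).
* `placements.tsv` — clone_id, category, chromosome, start, end,
  strand for every clone (all categories).
* `insert_stats.json` — mean, sd, n_used, n_rejected, iterations,
  sd_window, lower/upper acceptance bounds.
* `summary.tsv` — library summary counts plus derived percentages.
* `coverage.tsv` — per-chromosome rows then aggregate rows
  (autosome/X/Y, genome, genome_excl_Y): chromosome, total_chr_length,
  nonredundant_clone_length, clone_length_total,
  passed_aligned_sequence, clone_depth, pct_total_coverage.
* `variants.vcf` — VCF 4.2; SNPs as-is, DIPs left-anchored with the
  `CANDIDATE_DIP` INFO flag; `SUPPORT` = supporting read count.
* `truth.json` (simulator) — true clone positions and expected
  categories, planted variants, repeat copy locations.
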