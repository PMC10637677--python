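# barcodegap

A toolkit for DNA-barcoding gap analysis and threshold-based species
identification from pre-aligned nucleotide sequences:

- **Distances** — Kimura 2-parameter (K2P) and raw p-distance matrices with
  pairwise deletion of gap/ambiguous columns; saturated pairs are itemized,
  never silently clamped.
- **Thresholds** — three estimators: kernel-density local minima of the
  pooled distance distribution, grid search minimizing cumulative
  identification error (false negatives + false positives), and the
  95%-intraspecific-percentile rule. All estimates are reported; the
  package never auto-adjudicates between methods.
- **Identification** — best-close-match (BCM) with four statuses
  (`correct` / `incorrect` / `ambiguous` / `no_id`), nearest-neighbour tie
  handling, and an optional strict-ambiguity mode.
- **Diversity** — haplotype count, haplotype diversity (Nei & Tajima),
  segregating sites, and nucleotide diversity (mean pairwise p-distance).
- **Gap summaries** — per-sequence max-intra / min-inter extremes,
  per-species mean/range tables, and a global gap test.
- **Synthetic communities** — a seeded generator of labeled barcode
  communities with controlled intra/interspecific divergence, a tunable
  transition:transversion ratio, optional singletons, and an overlap mode
  that plants a shared haplotype across two species (the regime in which
  thresholds necessarily fail).

## Input formats

- Aligned multi-FASTA (all sequences the same length; `U` is mapped to `T`,
  IUPAC ambiguity codes other than `N` are normalized to `N`).
- A tab-separated label table with header `id<TAB>species`. The species
  column accepts the reserved tokens `OUTGROUP` and `UNIDENTIFIED`
  (case-insensitive) to mark sequences the exclusion filter can remove.

Before gap analysis the filter drops (each independently toggleable)
unidentified sequences, outgroups, and singleton species — singletons
being species with exactly one sequence left *after* the first two drops.

## CLI

```sh
# simulate a clean-gap community
barcodegap simulate --out-prefix demo --n-species 4 --per-species-n 10 \
    --length 600 --intra 0.01 --inter 0.15 --seed 1

# full pipeline: filter -> distances -> thresholds -> BCM -> diversity -> gap tables
barcodegap run demo.fasta demo.labels.tsv --outdir demo_out

# individual stages
barcodegap distances demo.fasta demo.labels.tsv --out dm.tsv
barcodegap thresholds demo.fasta demo.labels.tsv --out thresholds.json
barcodegap identify demo.fasta demo.labels.tsv --threshold 0.006 --out id.tsv
barcodegap diversity demo.fasta demo.labels.tsv
barcodegap gaptable demo.fasta demo.labels.tsv --out-species sp.tsv --out-long long.tsv
```

Alignment trimming (`--trim-start/--trim-end`, 1-based inclusive columns)
is available on every subcommand. Thresholds appear in every artifact both
as proportions and percentages. Exit codes: 0 ok, 2 input error, 3
degenerate-data condition (e.g. nothing left after filtering).

`run` writes a report bundle: square distance-matrix TSV, threshold JSON
(all three methods with density-curve and error-grid TSVs), per-sequence
identification TSVs at each estimated threshold, a diversity JSON, a
per-species distance table, a long-format per-sequence gap table, and a
manifest logging configuration and exclusions. Re-running with the same
inputs reproduces the bundle byte-for-byte (manifest aside).

## Library use

```python
from barcodegap import (
    read_labeled_fasta, apply_filter, FilterPolicy,
    pairwise_distance_matrix, optimize_threshold, percentile_threshold,
    local_minima_threshold, best_close_match, diversity_summary,
    build_gap_table, gap_exists,
)

aln = read_labeled_fasta("coi.fasta", "coi.labels.tsv", locus="COI")
aln, log = apply_filter(aln, FilterPolicy())
dm = pairwise_distance_matrix(aln, model="K2P")
t = optimize_threshold(dm, aln.labels).value
report = best_close_match(dm, aln.labels, t)
print(report.counts, report.proportions)
```
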