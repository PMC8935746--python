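# stemsc

A rank-based, batch-robust stemness index for bulk and single-cell
transcriptomes, built on relative expression orderings (REOs) of gene
pairs.

Because the index only consumes the within-sample *order* of gene-pair
expression values, it is exactly invariant to any strictly increasing
per-sample transform (RPKM vs TPM vs log, scaling, power distortions),
which makes it usable across datasets without batch correction.

## What it does

1. **Stable REOs** (`stemsc.reo`) — find the gene pairs whose strict
   ordering is identical in every sample of a dataset; quantify
   cross-dataset agreement of two stable-REO sets (s/n) with a
   cumulative binomial significance model.
2. **Signature training** (`stemsc.training`) — select genes Spearman-
   correlated with differentiation time (per-dataset BH-FDR, intersected
   across all time courses), then keep the gene pairs stable with a
   concordant direction in both a pooled single-cell and a pooled bulk
   reference (stem-cell-like) collection.
3. **Scoring** (`stemsc.scoring`) — score any sample as k/n: the
   fraction of evaluable reference pairs whose ordering matches the
   reference direction.
4. **Downstream analyses** (`stemsc.analysis`) — gene ranking by score
   correlation, pre-ranked running-sum enrichment, hypergeometric
   overlap tests, reference-guided score thresholding and stem-like
   calling, trajectory-root selection (highest mean score per state),
   highly-variable-gene selection (variance/mean), and two-group
   t-tests.
5. **Synthetic data** (`stemsc.simulate`) — seeded generators for
   differentiation time courses with planted monotone genes, reference
   pools around one latent ordering, two-component stem/differentiated
   mixtures, per-sample monotone batch distortions, and dropout.
6. **I/O + CLI** (`stemsc.io`, `stemsc.cli`) — dense TSV/CSV and
   Matrix-Market triplet readers/writers, signature/score/panel TSVs,
   cell QC filtering, and gene-ID mapping.

## CLI

```bash
# generate synthetic training data
stemsc simulate course --seed 1 --out-dir data/course1
stemsc simulate pool  --seed 1 --n-sc 2 --n-bulk 2 --out-dir data/pool

# train a signature (time courses need a <stem>.meta.tsv with a 'time' column)
stemsc train --time-dataset data/course1/course.tsv \
             --time-dataset data/course2/course.tsv \
             --sc-pool data/pool/esc_sc_0.tsv --sc-pool data/pool/esc_sc_1.tsv \
             --bulk-pool data/pool/esc_bulk_0.tsv --bulk-pool data/pool/esc_bulk_1.tsv \
             --fdr 0.05 -o signature.tsv --panel-out panel.txt

# score samples, pick a threshold, find a trajectory root
stemsc score --matrix data/course1/course.tsv --signature signature.tsv -o scores.tsv
stemsc threshold --scores scores.tsv --labels labels.tsv
stemsc root --scores scores.tsv --states states.tsv

# other utilities
stemsc consistency --set-a a.tsv --set-b b.tsv
stemsc enrich --ranking ranking.tsv --geneset markers.txt --nperm 1000 --seed 1
stemsc hvg --matrix matrix.tsv --min-cells 10 --top 5000
```

All commands exit nonzero with a diagnostic on invalid input; `--quiet`
suppresses informational logging.

## Conventions

- Dense matrices: genes as rows, first header column `gene`, samples as
  the remaining columns.
- Pair files: TSV with header `gene_high\tgene_low`, meaning
  expression(gene_high) > expression(gene_low), lexicographically
  ordered lines.
- Score files: TSV `sample\tn_evaluable\tk_concordant\tstemsc`;
  undefined scores (no evaluable pair) are written as `NA`.
- Ties disqualify: a pair tied in any sample is not stable, and a tied
  pair in a scored sample is excluded from n.
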