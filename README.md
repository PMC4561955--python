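# hybridexpr

Hybrid-vs-parents expression analysis for unreplicated RNA-seq trios
(maternal parent P1, paternal parent P2, hybrid generations F1 and F2):

- **FPKM normalization** (`10^9·C/(N·L)`) and **median-of-ratios size
  factors** for between-library scaling.
- **Exact differential expression without replicates** via the
  Audic–Claverie conditional count test, Benjamini–Hochberg FDR, and a
  strict two-fold change gate (`FDR ≤ 0.001`, fold change > 2 for genes;
  `q < 0.05` for miRNAs).
- **Mid-parent-value (MPV) additivity testing**: each hybrid is tested
  against the average of its parents' normalized expression.
- **Twelve-bin expression-level-dominance classification**: the three
  pairwise comparisons (P1 vs P2, hybrid vs P1, hybrid vs P2) place each
  gene into one of twelve bins grouped as additivity {I, XII}, dominance
  toward P1 {II, XI}, dominance toward P2 {IV, IX}, transgressive up
  {V, VI, VIII}, transgressive down {III, VII, X}, conserved, or
  ambiguous.
- **Cross-generation inheritance** of categories (F1 ∩ F2 per label) and
  percentage-style summary reporting.
- **miRNA layer**: the same machinery applied to miRNA counts, plus
  Pearson anticorrelation between miRNA and target-gene log2 fold
  changes (one pair per miRNA→target link).
- **Hypergeometric term enrichment** with BH-FDR and
  observed-vs-expected percentages.
- **Synthetic-data generator**: four unreplicated negative-binomial
  libraries over log-normal baselines with planted conserved / additive /
  dominance / transgressive / sample-specific genes, configurable F1→F2
  inheritance, and a miRNA layer whose targets' fold changes are
  negatively coupled to the miRNA fold changes — with per-gene truth
  labels for recovery testing.

## CLI

```sh
# generate a synthetic dataset with truth labels
hybridexpr simulate --out sim/ --n-genes 2000 --n-mirnas 200 --seed 1

# sanity-check input files
hybridexpr validate --counts sim/counts.tsv --gene-meta sim/gene_meta.tsv \
    --mirna-counts sim/mirna_counts.tsv --targets sim/targets.tsv

# full pipeline: DE, MPV, classification, inheritance, miRNA, enrichment
hybridexpr run --counts sim/counts.tsv --gene-meta sim/gene_meta.tsv \
    --mirna-counts sim/mirna_counts.tsv --targets sim/targets.tsv --out out/
```

`run` writes per-pair DE tables, per-generation classification tables,
miRNA classifications, the miRNA–target pair table and correlation,
an enrichment table, `summary.tsv`/`summary.json`, and a `manifest.json`
recording the config, seed, and input digests. Individual stages are
also available as subcommands (`normalize`, `de`, `classify`, `inherit`,
`mirna`, `enrich`), each accepting `--config config.yaml` plus override
flags (`--fdr-gene`, `--fdr-mirna`, `--min-fold`, `--min-fpkm`,
`--seed`).

All inputs and outputs are plain TSV (UTF-8, `#` comments ignored; a
`#library_sizes` directive in a count table supplies explicit
mapped-fragment totals). Outputs are byte-stable for a fixed config and
seed.

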