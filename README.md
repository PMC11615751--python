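# acetylink

Integrative histone-acetylation (H3K27ac) ChIP-Seq / RNA-Seq analysis pipeline:

- **genomic_io** — BED/narrowPeak, GTF/BED6, TSV count matrices and sample
  sheets, all held internally in 0-based half-open coordinates; strict
  validation (malformed input is rejected with the offending line number).
- **signal_quant** — depth- and peak-length-normalized ChIP density with
  background-scaled input subtraction (floored at zero), per-gene FPKM, and
  optional `samtools bedcov`-style quantification of an indexed BAM.
- **differential_stats** — median-of-ratios size factors, a self-contained
  negative-binomial two-group Wald test (method-of-moments dispersion),
  Benjamini–Hochberg adjustment, Pearson/Spearman correlation with a t-based
  p-value, and hypergeometric over-representation against GMT gene sets.
- **integration** — TSS-window peak-to-gene linking (default ±1 Mb, boundary
  inclusive, many-to-many), per-link peak–gene correlation across samples,
  strict-threshold four-way PP/NN/PN/NP classification (|ChIP log2FC| > 1,
  |RNA log2FC| > 5), quadrant summaries and top-pair ranking.
- **synthetic_data** — a deterministic coupled ChIP/input/RNA count simulator
  that plants PP/NN/PN/NP pairs (plus uncoupled nulls) with per-sample latent
  factors inducing the assumed peak–gene correlation, and recovery scoring.
- **workflow / cli** — stage orchestration with a TOML config, a run
  manifest, and a `run-all` that reproduces the full synthetic experiment.

## CLI

```sh
acetylink run-all --seed 7 --out run7/            # full synthetic experiment
acetylink simulate --seed 7 --out sim/            # dataset only
acetylink link --peaks peaks.bed --genes genes.gtf --window 1000000 --out links.tsv
acetylink diff --counts chip_counts.tsv --samples samples.tsv --assay chip --out chip_diff.tsv
acetylink classify --links links.tsv --chip-diff chip_diff.tsv --rna-diff rna_diff.tsv \
    --chip-lfc 1 --rna-lfc 5 --r-min 0.5 --p-max 0.05 --out classified.tsv
acetylink summarize --links classified.tsv
```

Other subcommands: `quantify`, `fpkm`, `correlate`, `rank`, `enrich`.
Exit codes: 0 success, 2 validation error, 1 internal error. Sample sheets
accept `ND`/`MASLD` as aliases for `control`/`case`.

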