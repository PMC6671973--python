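# lncregnet

Analysis pipeline for paired two-condition microarray experiments profiling
mRNA and lncRNA probes together:

- **io_formats** — tab-separated expression matrices with Agilent-style
  P/A/M detection flags, probe annotations (1-based inclusive coordinates),
  paired sample designs, GMT gene sets, SIF/GraphML network export.
- **synthetic** — paired-design data generator with planted, recoverable
  ground truth: differential probes, negatively coupled lncRNA–mRNA pairs
  (exact target Pearson r, cis within a genomic window / trans across
  chromosomes) and TF-coregulated modules; byte-identical under a fixed seed.
- **preprocess** — log2 transform, classic quantile normalization
  (rank-wise reference means, deterministic tie handling), present-flag
  filtering ("flagged P in at least one condition").
- **diffexpr** — paired t-test on per-patient log2 differences, fold change
  with direction, Benjamini–Hochberg FDR, inclusive threshold selection
  (FC ≥ 2, P ≤ 0.05 by default).
- **coexpression** — genome-wide lncRNA×mRNA Pearson screening across all
  arrays, strong-negative pair selection (r ≤ −0.9, corr P ≤ 0.05),
  cis/trans classification by a 100-kb window with a stricter correlation
  bound (P ≤ 0.01), per-chromosome pair counts, paired permutation null.
- **enrichment** — hypergeometric over-representation analysis and lncRNA
  functional prediction via co-expressed mRNAs.
- **tf_network** — lncRNA–TF association by hypergeometric overlap with TF
  target sets, bipartite and tripartite network construction, summaries.
- **power_analysis** — patient-level bootstrap power curves and minimum
  sample size per gene.
- **pipeline / cli** — YAML-driven orchestration with a JSON run manifest.

## CLI

```bash
# end-to-end run from a YAML config (simulation-backed or file-backed)
lncregnet run --config config.yaml --seed 1 --outdir out/

# individual stages
lncregnet simulate --seed 1 --outdir data/
lncregnet preprocess --matrix data/matrix.tsv --flags data/flags.tsv \
    --design data/design.tsv --outdir out/
lncregnet de --matrix out/normalized_matrix.tsv --design data/design.tsv \
    --annotation data/annotation.tsv --outdir out/
lncregnet coexpr --matrix out/normalized_matrix.tsv --design data/design.tsv \
    --annotation data/annotation.tsv --outdir out/
lncregnet power --matrix out/normalized_matrix.tsv --design data/design.tsv \
    --annotation data/annotation.tsv --gene GENE00042 --outdir out/
```

Minimal simulation-backed config:

```yaml
seed: 1
simulate: {n_mrna: 2000, n_lncrna: 1000}
de: {fc_min: 2.0, p_max: 0.05}
coexpr: {r_max: -0.9, cis_window: 100000}
power: {sample_sizes: [3, 4, 5], n_bootstrap: 200, q_max: 0.5}
```

A file-backed run replaces the `simulate:` block with
`input: {matrix: ..., flags: ..., design: ..., annotation: ...,
function_gmt: ..., tf_gmt: ...}`.

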