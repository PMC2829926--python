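# traitsig

Quantitative-trait gene signature discovery for expression studies, with
qRT-PCR validation analytics and promoter motif over/under-representation
analysis — plus a synthetic-data generator so the whole pipeline is testable
without external data.

The pipeline targets studies where per-sample log expression is related to a
continuous clinical covariate (the default is percent weight loss, with
weight-losing subjects defined at ≥ 5 % and systemic inflammation at
CRP ≥ 5 mg/l):

1. **simulate** (`traitsig.simulate`) — synthetic studies with planted
   trait-correlated genes (slope calibrated so a target Pearson |r| is the
   population correlation), promoter sets with motif occurrences planted at
   per-promoter Poisson rates, and triplicate qPCR Ct tables.
2. **filter** (`traitsig.study`) — TSV IO (expression matrix, P/M/A
   detection flags, clinical table) and the pre-analysis filters: drop genes
   absent on every array, optionally drop low-SD genes.
3. **discover** (`traitsig.discovery`) — two independent procedures:
   a quantitative-response SAM statistic `d = slope/(se + s0)` with a seeded
   covariate-permutation FDR, and an empirical-Bayes moderated regression t
   with Benjamini–Hochberg FDR. Genes called by both at the FDR bound
   (default < 0.10) with agreeing direction form the signature; per-gene
   Pearson coefficients are reported alongside.
4. **cluster / validate** (`traitsig.validation`) — subject clustering on
   signature genes (hierarchical with 1 − Pearson distance, or k-means)
   scored against the WL/WS labels; ΔCt quantification
   (`rel = 2^(−ΔCt)`, 18S reference); cross-platform concordance
   (sign agreement + qPCR regression p < α); comparative marker-panel
   group-mean analysis.
5. **motifs** (`traitsig.motifs`) — JASPAR-format PFMs → log₂-ratio matrices
   against a uniform background (pseudo-count 1), both-strand scanning with a
   hit threshold at 0.8 of the matrix scoring range, per-sequence Fisher
   exact test and per-base-pair Z-score against a background promoter set,
   heatmap-ready z matrix. A small built-in motif collection ships with the
   package (`traitsig.motifs.builtin_motifs()`).

## Command line

One executable with per-stage subcommands:

```sh
traitsig simulate --out-dir run/ --n-genes 2000 --seed 7
traitsig discover --expression run/expression.tsv --detection run/detection.tsv \
    --clinical run/clinical.tsv --fdr-bound 0.10 \
    --stats-out run/gene_stats.tsv --signature-out run/signature.tsv
traitsig cluster  --expression run/expression.tsv --detection run/detection.tsv \
    --clinical run/clinical.tsv --signature run/signature.tsv --out run/clusters.tsv
traitsig motifs   --fg run/fg_promoters.fasta --bg run/bg_promoters.fasta \
    --out run/motif_enrichment.tsv --heatmap-out run/motif_heatmap.tsv
traitsig run-all  --config pipeline.cfg     # flat key=value config
```

`traitsig run-all` executes simulate → filter → discover → cluster →
validate → motifs, writing every intermediate table plus a `manifest.json`
recording the config hash, per-stage seeds and row counts; identical configs
reproduce identical numeric outputs.

## Layout

```
src/traitsig/
  simulate.py    synthetic studies, promoter sets, Ct tables
  study.py       ExpressionStudy container, TSV IO, filters
  discovery.py   SAM quantitative, moderated test, Pearson, intersection
  validation.py  clustering, delta-Ct, concordance, marker panels
  motifs.py      PFM parsing, scanning, Fisher/Z enrichment, heatmap
  pipeline.py    run_pipeline + flat key=value PipelineConfig
  cli.py         click entry point (`traitsig`)
  data/pfms/     built-in JASPAR-format motif collection
```
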