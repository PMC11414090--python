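# callimorph

Quantitative analysis of marmoset (*Callithrix*) hybrid morphometrics:
per-taxon trait statistics, heterogeneous-variance screening, mid-parent-value
classification of hybrid traits, morphospace PCA, and between-group
mitogenomic distance estimation — with a synthetic-data generator so every
stage is verifiable without external downloads.

## What it does

* **trait_io** — read/validate individual-level trait tables (13 traits, six
  measured left/right and averaged), filter to adults, normalize to a flat
  13-trait matrix.
* **stats_core** — group summaries, Levene/Brown–Forsythe, Welch's one-way
  ANOVA, Games–Howell post-hoc (studentized-range calibrated, numeric
  quadrature CDF accurate to ~1e-6), one-sample and Welch two-sample t-tests
  from (n, mean, SD) summaries, Pillai-trace MANOVA.
* **hybrid_classification** — mid-parent values (MPV) and per-trait labels:
  transgressive, heterotic, dysgenetic, intermediate, parental-like, or
  outside-range nonsignificant; works from raw tables (`classify_all`) or
  from published summary statistics alone (`summary_mode_classify`).
* **morphospace** — PCA of the 13-trait matrix (correlation or covariance
  scaling, listwise deletion, deterministic sign convention).
* **genetic_distance** — Tamura–Nei (1993) distances with composite-likelihood
  parameter estimation, pairwise deletion, and between-group mean distances.
* **synthetic_data** — trait tables under additive / heterotic / dysgenetic /
  transgressive / parental-like regimes, and TN93 sequence alignments on a
  star tree, both with ground-truth bookkeeping.
* **cli / pipeline** — end-to-end orchestration with a run manifest.

## CLI

```sh
callimorph simulate --seed 3 --out raw.csv
callimorph ingest --traits raw.csv --out clean.csv --report report.json
callimorph summarize --traits clean.csv --out summaries.csv
callimorph classify --traits clean.csv --out labels.csv
callimorph pca --traits clean.csv --subset J,P,PJ --outdir pca/
callimorph gdist --fasta aln.fa --groups groups.tsv --out dist.csv
callimorph run --config run.yaml
```

`run.yaml` needs at least `traits_path` and `out_dir`; optional keys:
`fasta_path`, `groups_path`, `plan`, `alpha`, `pca_subsets`, `pca_scaling`,
`seed`.

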