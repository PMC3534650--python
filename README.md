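# ccam

Constrained ordination of gene-expression matrices: a disease (or otherwise
"to be explained") gene × sample matrix is standardised in the chi-square
metric, regressed onto per-population averages of a well-characterised
reference dataset, and decomposed by SVD. The resulting axes carry gene,
sample and environment-arrow scores that support triplot maps, axis-derived
prognostic scores and survival analyses — all verifiable end to end on
synthetic data with known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `ccam.preprocess` | load/align/z-score matrices, nonnegativity shift, empirical-Bayes batch adjustment |
| `ccam.signatures` | moderated-t (empirical-Bayes shrinkage) one-vs-rest signatures, Pearson signature scoring, signature clustering |
| `ccam.cca_core` | chi-square form, weighted projection onto environment variables, SVD, lc/wa/sample/arrow scores, inertia decomposition |
| `ccam.scoring` | top/bottom-gene axis scores per sample, percentile stratification |
| `ccam.survival_stats` | Kaplan-Meier, k-sample log-rank, Cox PH (Efron ties), Kruskal-Wallis / Mann-Whitney with Bonferroni |
| `ccam.synthetic_fixtures` | seeded generators: marker-block reference populations, Dirichlet-mixture disease cohorts, proportional-hazards survival |
| `ccam.viz_cli` | triplot layout (centroids, 95% ellipses, angular nearest-arrow assignment), static rendering, CLI |

## CLI

All stages read/write plain TSV/YAML; outputs are byte-stable for a fixed
seed and inputs.

```sh
ccam demo --seed 1 --out-dir out/demo          # full synthetic pipeline
ccam prepare --expr disease.tsv --ref ref.tsv --out-dir out/prep
ccam signatures --ref out/prep/ref_prepared.tsv --annotation ref_ann.tsv --out-dir out/sig
ccam fit --expr out/prep/expr_prepared.tsv --ref out/prep/ref_prepared.tsv \
         --annotation ref_ann.tsv --populations POP1,POP2,POP3 --out-dir out/fit
ccam score --fit-dir out/fit --expr out/prep/expr_prepared.tsv --cuts 50,95 --out-dir out/score
ccam survival --scores out/score/scores.tsv --clinical clinical.tsv --out-dir out/surv
ccam plot --fit-dir out/fit --out-dir out/plot
```

Expression input: genes in rows, first column gene ids, header row of sample
ids. Annotation: TSV with `sample_id`, `group`, optional `batch` and clinical
columns. Clinical: `sample_id`, `time`, `event` (0/1), covariates.

## Notes

- The chi-square metric requires nonnegative input; `shift_nonnegative`
  offers `global_min` (default) and `clip_zero` handling for z-scored data.
- Axis signs are fixed by orienting each axis so its largest-|loading|
  environment arrow is positive.
- Cross-level similarity on triplots uses angular distance, not Euclidean.
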