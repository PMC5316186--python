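# stagedyn

Staged tumor-vs-control transcriptomic dynamics, as a tested, reusable
pipeline. The target design is the four-stage progression of the MMTV-PyMT
mouse model of breast cancer — hyperplasia (week 6), adenoma/MIN (week 8),
early carcinoma (week 10), late carcinoma (week 12), each with tumor and
age-matched control replicates — but any gene × sample count matrix with
such a sample sheet works. It is written for computational biologists who
want each analysis stage available as a library function, a CLI subcommand,
and a testable unit with synthetic data carrying planted truth.

## What it computes

- **Filtering + normalization** — genes with CPM < 1 in more than half of
  the samples are removed; size factors by the median-of-ratios estimator,
  s_j = median_i (x_ij / geomean_i); plus the qPCR 2^−ΔΔCt fold-change
  utility.
- **Per-stage differential expression** — a negative-binomial conditional
  exact test per gene at each week (tumor vs control), with a Cox–Reid
  adjusted common dispersion, moment-based per-gene shrinkage, BH adjustment
  within stage, and DEG calls at fold change > 2, FDR < 0.05; cross-stage
  Venn accounting of the four DEG sets.
- **PCA + covariate association** — sample PCA of log-normalized expression
  on top-variance genes; −log10 p of regressing top PC scores on known
  covariates (condition, stage, litter, batch, age).
- **Transition patterns** — per gene, LRC_i = log2R^(i+1) − log2R^(i) over
  the three inter-stage transitions, z-scored across genes and trinarized at
  ±τ SD into {−1, 0, +1}; 3³ = 27 possible patterns, each with a fixed
  group id and a flag for a non-constant second (malignant) transition.
- **Trend clustering** — top-1000 PC-loading genes, ratio vectors of mean
  tumor expression at weeks 8/10/12 relative to week 6, k-means with the
  elbow (maximal WSS second difference) choosing k.
- **Co-expression modules** — signed adjacency ((1+cor)/2)^β, topological
  overlap, average-linkage clustering with a static cut; module eigengenes
  (PC1), hub genes by intramodular connectivity, eigengene–stage Spearman
  association with a 10,000-label-permutation p-value, and a simplified
  two-statistic preservation Z-summary (thresholds 2 / 10).
- **Enrichment** — hypergeometric over-representation of DEG lists against
  GMT gene-set collections.
- **Synthetic data** — NB counts with library-size variation and planted
  constant/progressive DEGs, transition-pattern genes, and latent-factor
  co-expression modules tracking stage, with a per-gene truth table.

See `docs/methods.md` for the statistical details and defaults.

## Worked example

```python
from stagedyn.simulate import SimulationConfig, simulate_dataset
from stagedyn.pipeline import PipelineConfig, run_pipeline

dataset = simulate_dataset(SimulationConfig(n_genes=2000, rng_seed=1))
config = PipelineConfig(out_dir="demo_out", seed=1)
result = run_pipeline(config, counts=dataset.counts, sheet=dataset.sample_sheet)

print("genes after filtering:", result.filtered_counts.shape[0])
for week, counts in result.overlap["per_stage"].items():
    print(f"  {week}: {counts['total']} DEGs ({counts['up']} up, {counts['down']} down)")
print("DEG union:", result.overlap["union"],
      "| in all four stages:", result.overlap["all_stages_intersection"],
      f"({result.overlap['all_stages_fraction']:.1%})")
print("trend clusters: k =", result.trend_clusters.chosen_k)
print(result.stage_association[["module", "rho", "pvalue"]].round(4).to_string(index=False))
```

prints

```
genes after filtering: 1996
  w6: 102 DEGs (55 up, 47 down)
  w8: 172 DEGs (112 up, 60 down)
  w10: 230 DEGs (138 up, 92 down)
  w12: 236 DEGs (143 up, 93 down)
DEG union: 270 | in all four stages: 90 (33.3%)
trend clusters: k = 2
 module   rho  pvalue
      1 0.904  0.0001
```

DEG counts rise with stage (the planted progressive and transition effects
cross the fold-change gate only at later weeks), a third of the DEG union is
differential at every stage (the planted constant effects), and the detected
co-expression module's eigengene tracks ordinal stage (Spearman ρ = 0.90)
with the permutation p at its floor of 1/(B+1).

The same run from a shell:

```sh
stagedyn simulate --out sim --n-genes 2000 --seed 1
stagedyn all --counts sim/counts.tsv --samples sim/samples.csv --out demo_out --seed 1
```

Individual stages are available as subcommands (`preprocess`, `deg`,
`patterns`, …); `stagedyn all --help` lists the tuning flags
(`--fc-threshold`, `--fdr`, `--tau`, `--beta`, `--permutations`, `--k`,
`--top-trend-genes`).

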