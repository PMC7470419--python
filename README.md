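# scprognosis

Prioritizes cancer-prognosis gene signatures from single-cell RNA-seq of the
epithelial-to-mesenchymal transition (EMT), and validates them on bulk
expression cohorts with survival follow-up. It is aimed at computational
biologists who have (a) an scRNA-seq matrix of cells traversing EMT and (b)
a bulk cohort with survival outcomes, and want a ranked gene list whose top
N genes act as a prognostic signature.

## Method

Cells are placed on a linear E→M axis by a pseudotime score *t* ∈ [0, 1],
either from the mesenchymal marker VIM's expression rank ("VIM-time") or
from an ensemble of randomized shortest paths on l-out-of-k nearest-neighbor
graphs ("W-time"). The matrix is first denoised by Markov diffusion
(PCA → adaptive Gaussian kernel → symmetrized, row-normalized transition
matrix **M**, imputed data = **M**ᵗ · raw) and filtered for low
coverage/expression. Three per-gene importance measures are then computed:

- **MAD(g)** = median(|e − median(e)|), the expression variability across
  cells;
- **SDE(g)** = |k̂_g|, the slope of the maximum-likelihood sigmoid fit
  f(t) = 2μ₀ / (1 + exp(−k(t − t₀))) of the gene against pseudotime
  (switch-like differential expression), zeroed when the BH-adjusted
  likelihood-ratio test is non-significant;
- **NET(g)**, the fixed point of the modified PageRank recursion
  NET(g) = (1 − d)/G + d · Σ_{tg ∈ T(g)} NET(tg)/L(tg) on the directed
  co-expression network whose edges g → tg are statistically significant
  maximum absolute lagged Pearson correlations (MAC) over lags
  l ∈ {0, …, C/3} of the pseudotime-ordered series.

Each measure is normalized to sum 1 over genes and combined as
W(g) = α·MAD′ + β·SDE′ + γ·NET′ with α + β + γ = 1; genes are ranked by
descending W, with (α, β, γ, N) tunable by grid search over the weight
simplex against cross-validated survival performance. The top-N genes feed
a Cox proportional-hazards model h(t|X) = h₀(t)exp(β′X); patients are
scored by r = β′(X − mean(X_train)), split at the median score into
high/low risk groups, and evaluated by the censoring-aware concordance
index (C-index), the between-group hazard ratio, and Kaplan–Meier curves
with a log-rank test, under repeated k-fold cross-validation.

## Worked example

```python
from scprognosis import (ScSimConfig, simulate_emt_scrnaseq,
                         simulate_bulk_survival, PipelineConfig, run_pipeline)

mat, truth = simulate_emt_scrnaseq(ScSimConfig(seed=1))      # 500 x 600 EMT course
bulk = simulate_bulk_survival(truth.signature, n_samples=500,
                              censor_rate=0.3, seed=2, genes=list(mat.gene_ids))
config = PipelineConfig(out_dir="out", seed=1, weights=(0.2, 0.4, 0.4), top_n=10)
result = run_pipeline(config, sc=mat, bulk=bulk)
print(result.signature)
print({k: round(v, 3) for k, v in result.report.items()
       if isinstance(v, float)})
```

prints the 10-gene signature — switch-like genes of the simulated course —
and its evaluation on the bulk cohort:

```
['SW0017', 'SW0014', 'CDH1', 'SW0001', 'SW0013', 'SW0004', 'SW0003',
 'SW0006', 'SW0015', 'SW0012']
{'train_cindex': 0.693, 'cv_cindex': 0.683, 'cv_hr': 2.543,
 'hazard_ratio': 2.735, 'logrank_p': 0.0}
```

`cv_cindex` ≈ 0.68 means that in ~68% of comparable patient pairs the
patient who failed earlier had the higher predicted risk (0.5 is chance);
the hazard ratio ≈ 2.7 is the relative event rate of the high- vs low-risk
group, and the log-rank p-value confirms the two survival curves separate.

The same pipeline runs from the shell:

```
scprog simulate sc --out-prefix sim/ --seed 1
scprog run --sc sim/matrix.tsv --no-survival --out-dir out --seed 1
```

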