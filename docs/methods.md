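# Methods

## Model and assumptions

The pipeline assumes EMT is a *linear* continuum: every cell occupies one
point on an E→M axis, and a single pseudotime scalar t ∈ [0, 1] per cell
captures its progress. Branching trajectories are out of scope. Expression
units are treated as opaque non-negative reals; no library-size
normalization or log transform is applied.

Four model components carry the scientific content:

1. **Diffusion imputation.** Dropout (false zeros from failed capture) is
   repaired by averaging each cell with its transcriptional neighborhood:
   PCA on cells, Euclidean distances in PC space, an adaptive Gaussian
   kernel exp(−(d/σᵢ)²) with σᵢ the distance to the ka-th neighbor and
   affinities beyond the k-th neighbor zeroed, symmetrization
   (A + Aᵀ)/2, row normalization to a Markov matrix M, and imputation
   Mᵗ·raw. The operator is a convex combination of cell profiles, so
   non-negativity and row-stochasticity (rows of Mᵗ sum to 1) are exact.

2. **Pseudotime.** VIM-time is the rank of the mesenchymal marker's
   expression, min–max rescaled; ties share mean ranks. W-time builds the
   k-NN graph in 20-PC space, draws `n_graphs` subgraphs keeping l of each
   cell's k neighbors, and in each runs repeated randomized shortest paths
   from the start cell (the cell with minimal marker expression — the
   epithelial end), with multiplicative U(0.5, 1.5) edge-weight jitter per
   repetition; per-cell distances are averaged, rescaled to [0, 1], and
   oriented so the correlation with the marker is non-negative. A
   disconnected subgraph is an error rather than a silent misordering.

3. **Lagged co-expression (MAC).** With cells ordered by pseudotime, the
   association of an ordered gene pair (g, tg) is the maximum over lags
   l ∈ {0..C/3} of |Pearson(g[1..w], tg[1+l..w+l])| with a fixed window
   w = C − max_lag, so every lag uses the same sample size. The leading
   gene is the source. Significance comes from a permutation null — each
   gene's series shuffled independently, all pairwise MACs recomputed,
   null values pooled across pairs (resolution ~1/(n_perm·G²)) — with
   Benjamini–Hochberg adjustment over all tested ordered pairs.

4. **Gene scores and survival.** MAD, SDE and NET (definitions in the
   README), sum-normalized, convexly combined and ranked; the top-N genes
   enter a Cox proportional-hazards fit (Efron tie handling, Newton-type
   maximization via lifelines, optional L2 penalty for unstable designs),
   evaluated by the strict pairwise C-index (ties in score earn no
   credit), median-dichotomized hazard ratio (ties at the median go to the
   low-risk group), Kaplan–Meier/log-rank, and repeated event-stratified
   k-fold cross-validation with held-out predictions pooled within a run.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| n_pca, k, ka, t | 20, 30, 10, 6 | diffusion-imputation defaults; neighborhood and diffusion time of the Markov operator |
| k, l, n_graphs, reps | 25, 15, 20, 10 | W-time graph ensemble; jitter U(0.5, 1.5) per repetition |
| min_coverage | 0.1 | drop genes detected in <10% of cells |
| min_mean_expr | 10th pct of gene means | drop lowest-expression decile (data-dependent; pass an explicit value for idempotent re-filtering) |
| max_lag, window | C/3, C − max_lag | lag range and fixed correlation window |
| n_perm, fdr | 200, 0.05 | permutation count and BH edge threshold; pipeline desk default n_perm = 50 |
| d, tol, max_iter | 0.85, 1e-10, 1000 | PageRank damping and convergence |
| sde_q_threshold | 0.05 | BH gate below which SDE(g) = 0 |
| grid_step, N_candidates | 0.1, {5,10,15,20,30,50} | weight-simplex granularity (66 points at 0.1) and signature sizes |
| folds, runs | 10, 5 | repeated-CV protocol; `runs=100` reproduces the full 100×10 protocol via a flag |

## Numerical choices

- **Sigmoid fit.** Gaussian residuals with σ² profiled out, so the MLE
  minimizes the SSR via L-BFGS-B with analytic gradients; bounds
  μ₀ ∈ [0, 2·max(e)], k ∈ [−250, 250], t₀ ∈ [−0.5, 1.5]. Deterministic
  initialization (μ₀ = max/2, t₀ at the steepest smoothed change, k signed
  by late-minus-early means) plus the constant model as a fallback start
  and three seeded jittered restarts. Two safeguards matter in practice:
  fits pinned at the slope bound are flagged non-converged (the steepness
  is not identified at the sampling resolution, and a single unbounded
  slope would otherwise swallow the sum-normalized SDE column); and the
  likelihood-ratio statistic is scaled by an effective sample size
  n_eff = C(1−ρ)/(1+ρ) from the lag-1 autocorrelation ρ of the residuals
  ordered by pseudotime. Diffusion-imputed profiles have strongly
  autocorrelated residuals, for which the nominal χ²(2) test is wildly
  anti-conservative — without the correction essentially every smoothed
  noise gene tests significant. For independent residuals ρ ≈ 0 and the
  test reduces to the classical LRT.
- **SDE uses |k|**: down-regulated switch genes are as informative as
  up-regulated ones, and descending-W ranking plus sum normalization
  presume non-negative mass. A `signed` flag restores raw k.
- **MAC ties** across lags keep the smallest lag; zero-variance segments
  skip that lag; pairs with no valid lag are excluded.
- **NET** iterates the literal recursion from the uniform start 1/G with
  no dangling-mass redistribution (equivalently PageRank on the
  edge-reversed graph); isolated genes settle at (1−d)/G. The damping
  factor guarantees a contraction, so convergence is geometric.
- **Degenerate inputs** raise explicit errors: constant marker, all-zero
  cell, empty filter result, identical risk scores, no comparable pairs,
  no events.

## What the synthetic data emulates — and what it does not

`simulate_emt_scrnaseq` emulates an EMT time course: uniform latent
pseudotime; switch genes following the sigmoid law with μ₀ ∈ U(3, 6),
|k| ∈ U(8, 15), t₀ ∈ U(0.25, 0.75) (VIM increasing and CDH1 decreasing
always present); hub regulators as smooth band-limited waves (3–5 cycles
per course, baseline 6–8) whose m targets are lag-shifted copies along the
pseudotime ordering; lowly expressed stationary noise genes; and
value-dependent dropout P(zero|v) = min(1, c·e^(−λv²)) with c calibrated
so the expected zero fraction hits `dropout_rate`.

Three generator choices are deliberate. Hub waves carry mid-frequency
content because a regulator→target lag is only identifiable when the
signal's autocorrelation decays within a few dozen cells — slower waves
make the best-lag argmax ill-determined — and a multi-cycle wave is
non-monotone, keeping the hub/target class distinct from the switch-like
class under the sigmoid fit. Hub baselines sit above the dropout zone
(abundant regulators), because value-weighted dropout would otherwise
punch zero-valued steps into wave troughs that masquerade as switch-like
transitions. Flat genes are lowly expressed so dropout concentrates on
them and on pre-activation sigmoid tails, which is where capture failure
acts in real data.

The generator does **not** emulate UMI count distributions (negative
binomial noise), batch effects, doublets, or branching trajectories, so
passing tests demonstrate the pipeline's behavior under its own model
assumptions, not robustness to real-data artifacts beyond dropout.

The bulk generator draws log-normal expression and exponential survival
with hazard exp(Σ effect·z) on standardized planted-signature genes
(defaults ±0.5 alternating), with uniform censoring calibrated to the
target rate.

## Problem sizes

The standard study conditions used by the test-bed and by
`scripts/acceptance.py` are G = 500 genes × C = 600 cells, 20 switch
genes, 5 hubs × 8 targets, 30% dropout; bulk cohorts of 500 samples with
30% censoring; 5 runs of 10-fold CV (the 100-run protocol is a flag);
n_perm = 50 for pipeline permutation tests (module default 200). These
sizes keep a full run at a few minutes on one core while leaving every
statistical property measurable.

## Known limitations

- On heavily smoothed (diffusion-imputed) data the pooled permutation
  null for MAC is weak: smoothing inflates all lagged correlations, and
  the network approaches the complete graph. PageRank centrality is then
  nearly uniform, so hub recovery must come from sparser regimes; on
  correlation-derived networks in general, a hub's targets inter-correlate
  and no target has a small regulator count, which structurally caps how
  far Eq-style PageRank can elevate hubs above their targets.
- The pooled permutation null assumes pairs are exchangeable; genes with
  unusually strong autocorrelation receive slightly miscalibrated
  p-values.
- The LRT effective-sample-size correction is a first-order (lag-1 AR)
  approximation; heavy smoothing with long-range residual correlation can
  still leave the test anti-conservative.
- Weight tuning optimizes the cross-validated C-index; hazard-ratio-based
  selection can prefer different weights. Nested CV for unbiased
  performance reporting is not implemented.
- `filter_genes`' default mean-expression threshold is a percentile of the
  input, hence not idempotent; explicit thresholds are.
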