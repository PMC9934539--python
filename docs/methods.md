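# Methods

## Model

The engine treats deconvolution as learning a map `h` between two function
spaces on the reference latent space: the space of **rank-correlation
profiles** (one Spearman correlation per reference cell between a bulk
profile and that cell's neighborhood-aggregated expression) and the space of
**abundance distributions** (probability vectors over the J reference
cells).  Both are given D coordinates by projection through the
pseudoinverse of the latent loading matrix `Z` (J × D):
`x = Z⁺c`, `y = Z⁺p`, and `h` is a polynomial in `x` fitted by ordinary
least squares on simulated training pairs.  Inference expands `h(x)` back to
cells (`p = Z h(x)`) and renormalizes onto the simplex by subtracting the
most negative entry (if any) and dividing by the L1 norm.

Assumptions worth stating explicitly:

- The reference contains the cell states present in the query; the proximity
  score (distance of the query's `ŷ` to its 10 nearest training points,
  normalized by those points' mean pairwise distance) flags queries that the
  training family never approached, but cannot repair a missing state.
- Abundance distributions vary smoothly on the latent space.  Restricting
  `p` to the span of `Z` is the model's regularization: collinear cells
  (which induce identical gene rankings) are not separable from rank data,
  and the latent restriction removes exactly those unidentifiable
  directions.  The `rankdiag` tests demonstrate this on a collinear
  reference.
- Rank correlations, not expression magnitudes, carry the composition
  signal.  This makes every inference invariant to strictly monotone
  transforms of the bulk profile (tested bitwise).

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `scale` | library-size normalization target | 1e4 | counts → `log1p(count/libsize·scale)` |
| `n_var_genes` (T) | variable genes used for ranks and PCA | 2000 | binned-dispersion ranking |
| `n_dims` (D) | latent dimensions | 10 | PCA cell scores, sign-fixed for determinism |
| `n_neighbors` (r) | neighbors aggregated per cell | 5 | the cell plus its r nearest; r=0 disables |
| `degree` (s) | polynomial degree of `h` | 1 | degree 2 supported, not default |
| `n_train` (k) | training distributions | 5000 | k must exceed the monomial count |
| `n_sampled` (n) | cells per synthetic training bulk | J/2 | drawn with replacement |
| `m_range` | Gaussian-mixture components | [1, 5] | uniform |
| `sigma_percentile_range` | % of cells within 2σ of a center | [5, 20] | σ solved from the empirical distance quantile |

Mixture σ solving is exact rather than iterative: the 2σ radius is set to the
distance of the ⌈qJ⌉-th nearest cell to the center (q the sampled target
fraction), which meets a one-cell tolerance by construction.  The same
quantile construction sets the pseudotime-kernel σ in the simulator.

## Synthetic data

`simdata` emulates a standard gamma-Poisson single-cell generator: gene
baseline means are Gamma(0.6, rate 0.3); per-group (or per-branch-endpoint)
differential-expression factors are applied to a `de_prob` fraction of genes
with folded-log-normal magnitude `exp(|N(de_fac_loc, de_fac_scale)|)` and
reciprocal factors for a `de_down_prob` fraction; group profiles are
normalized to proportions; per-cell depths are log-normal (location 11,
scale 0.2); and each cell-gene count is Poisson around a gamma-jittered mean
whose coefficient of variation is `bcv_common + 1/sqrt(mean)`
(`bcv_common = 0.1`).  The folded magnitude guarantees that an up-designated
gene's stored factor is always > 1 (and a down gene's < 1), so the stored
factor table is an exact ground truth for calibration; at moderate-to-strong
`de_fac_loc` it is close to the plain log-normal.  The mean-dependent CV
term matters: without it, non-DE genes share identical Poisson dispersion,
variable-gene selection isolates the DE genes trivially, and recovery
becomes unrealistically easy.

Trajectory mode interpolates gene log-factors from each branch's parent
endpoint to its own endpoint over `n_steps` steps (logistic profiles with
random midpoints for a `nonlinear_prob` fraction of genes); pseudotime is the
cumulative step index from the root, and branch populations follow
`group_probs`.

Pseudo-bulks: discrete mode samples `n_k = round(f_k · n_cells / I)` cells
per type without replacement and sums their counts (fractions floored at
0.05 when sampled randomly); trajectory mode samples 1000 cells with
replacement proportional to a Gaussian kernel on pseudotime whose 2σ ball
captures a target number of cells (300–1500 at the 5000-cell reference
scale, rescaled proportionally at smaller scales).

What the simulator does **not** emulate: empirical mean–variance trends
fitted to real data, dropout beyond what the gamma-Poisson induces, batch
effects, doublets, or ambient contamination.  Passing recovery tests on
these simulations therefore demonstrates the engine's correctness under its
own generative assumptions, not performance on any particular real tissue.

## Numerical choices

- Genes are put in canonical (lexicographic) order at the start of training,
  so consistently permuted inputs yield bit-identical models and
  predictions.
- Spearman correlations are computed as one standardized rank-matrix
  product; constant rank vectors correlate as 0 with a warning instead of
  raising, so degenerate profiles cannot abort batch runs.
- PCA fixes each component's sign by making its largest-magnitude gene
  loading positive; `Z⁺` uses SVD with relative cutoff 1e-10; requesting
  more dimensions than the matrix rank truncates with a warning.
- Nearest-neighbor ties are broken by ascending cell index (stable argsort),
  and the aggregated column for cell j covers the cell **plus** its r
  neighbors (r+1 cells).
- Rank-deficient polynomial designs fall back to minimum-norm least squares
  with a warning.
- Expected values over cells (e.g. expected pseudotime) renormalize the
  probabilities over the kept subset (a conditional expectation); the
  optional IQR restriction keeps cells whose probability lies within
  [Q1, Q3] of the probability values (linear-interpolation quantiles).
  Filtering on probability quantiles — not on pseudotime — is the intended
  reading of this estimator; note it trims the distribution's peak,
  which stabilizes estimates on diffuse real-data distributions but can bias
  them when the true distribution is sharply peaked at a trajectory
  boundary (shown in `examples/trajectory_pseudotime.py`).
- Zero-variance axes in performance reports yield NaN correlations, never a
  silent 0; RMSE is still reported.
- Kendall tau distance is computed by merge-counting inversions
  (O(T log T)); the O(T²) definition is kept in the tests as the oracle.
- Spatial gradients snap spots to the lattice of unique x/y coordinates,
  use central differences where both lattice neighbors exist and one-sided
  differences at borders, flag isolated spots, and smooth vectors with a
  truncated Gaussian kernel (σ = 0 returns the raw gradient).

## Simulation-study scales

The recovery studies in `scripts/acceptance.py` and
`tests/test_acceptance.py` run at a desk scale chosen to finish in minutes
on one CPU while preserving the generative design of the full-scale studies:
2,000 cells × 5,000 genes per reference, 2,000 training distributions,
5 pseudo-bulks per configuration; the discrete grid covers 3/6/9 groups ×
`de_fac_loc` {0.01, 0.2, 0.6} (the minimum, median and maximum of the
full-scale 9-level grid) and the trajectory grid 3 topologies ×
`de_fac_loc` {0.4, 1.0}.  DE probability stays at its full-scale value
(0.0025), and the kernel capture window scales with the cell count.  The
DE-calibration runs use few cells per simulation because the factor table is
independent of the cell count.

## Known limitations

- The polynomial map is global and low-degree; queries far outside the
  training family (high proximity score) extrapolate poorly.
- Inferred abundances tend to compress the dynamic range of the truth
  (correlations are high, absolute ranges conservative), so downstream
  analyses should rely on relative comparisons across samples.
- Per-cell recovery on continuous trajectories is intrinsically noisier
  than per-type recovery, most visibly at weak differential expression.
- The latent restriction that regularizes the problem also caps resolution:
  abundance variation orthogonal to the top D components is invisible.
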