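# Methods

## Model and procedure

The package ranks genes from a two-group comparison by a lower confidence
bound on the magnitude of log2 fold change (LFC), with simultaneous
false-discovery-rate control. Three layers:

**Per-gene statistics.** Each gene contributes an LFC estimate `x`, a
standard error `s` and degrees of freedom `d`. These may be read from a
table (any moderated linear-model fit upstream will do) or computed
internally from a log2-expression matrix: the effect is the difference of
group means, the residual variance is the pooled within-group variance with
`n_A + n_B − 2` df, and empirical-Bayes moderation (below) shrinks the
variances and inflates the df.

**Threshold test.** The TREAT interval-null test of |LFC| ≤ e has p-value
`p(e) = SF((|x|−e)/s) + SF((|x|+e)/s)` with SF the t(d) survival function.
It reduces to the two-sided t-test at e = 0, is non-decreasing in e (the
density argument on the two tails), and is scale-equivariant: scaling x, s
and e together leaves p unchanged. Inverting the test at fixed level α
(largest e with p(e) ≤ α) gives a per-gene lower confidence bound on |LFC|,
signed by the sign of the estimate. A significant interval-null result also
pins down the sign; the bound statement adopts that convention.

**Nested selection.** At each grid threshold e = 0, Δ, 2Δ, … the largest
set `S(e) = {i : p_i(e) ≤ |S(e)| q / n_gene}` is computed. This
self-referential "largest set" definition equals classical BH step-up
selection at level q (verified in the test suite by brute-force subset
enumeration on small instances). Monotonicity of p in e makes the sets
nest, so the scan only re-tests surviving genes; it stops when the set
empties. The confect of gene i is the largest grid e with i ∈ S(e), signed
by the effect estimate. Genes with equal confects are ordered by their
p-value at the first threshold that excluded them; genes never selected are
appended in order of p(0); residual ties break on gene id, giving a
deterministic strict total order. By construction
`{i : |confect_i| ≥ e} = S(e)` for every grid value, and every confect
satisfies `p_i(|c_i|) ≤ |S(|c_i|)| q / n_gene`, which is exactly the
Benjamini–Yekutieli condition making the bounds FCR-valid for any
selection of the form "all genes with |confect| ≥ e"
(`ConfectResults.check_fcr_inequality` re-verifies it on every fit).

## Variance moderation

The variance prior is scaled inverse chi-square with df `d0` and scale
`v0`. Under it, sample variances follow a scaled F law, so `(d0, v0)` are
estimated in closed form by matching the mean and variance of the log
sample variances to the theoretical log-F moments: the excess spread of
`log s²` beyond the trigamma(df/2) sampling contribution determines `d0`
through a trigamma inversion (Newton iteration), and the mean fixes `v0`
through a digamma correction. Posterior variances are
`(d0 v0 + df s²)/(d0 + df)` — always between `s²` and `v0` — and the
moderated df are `df + d0`. When no excess spread is observed `d0 = ∞`:
all posterior variances equal `v0` (taken as the mean sample variance, its
unbiased estimate in that regime) and df are capped at 10⁶, where the t
distribution is numerically normal. Exact numeric agreement with other
moderation implementations is not promised; the contract is the convex
squeezing property and parameter recovery (within 15% on 10⁴ genes in the
tests). Zero-variance genes are retained when moderation is on (the prior
rescues their standard error) and dropped with a counted warning when it is
off. Unequal group sizes are supported.

## Tunable parameters

| parameter | default | units | role |
| --- | --- | --- | --- |
| `fdr` (q) | 0.05 | — | target FDR of every selection S(e); also the FCR level of the bounds |
| `step` (Δ) | 0.01 | log2 units | grid resolution of the confects; coarser grids only round bounds down (conservative) |
| `max_e` | 30 | log2 units | safety cap on the scan; reaching it truncates the top confects and records a warning (a 2³⁰-fold change is beyond any real assay) |
| `level` | 0.95 | — | CI level of the comparison rankers; the Bonferroni variant widens per-gene intervals to family level 1 − level |

## Simulation design

The generator emulates a moderated-t differential expression experiment,
with every distributional element chosen to stress the estimator rather
than flatter it:

- gene variances: `σ²_i = d_within s²_within / χ²(d_within)` — scaled
  inverse chi-square, the conjugate heteroscedasticity model;
- true LFCs: scaled t (`β_i / s_between ~ t(d_between)`, power-law tails;
  preset `sim1`: d_within = 2, s_within = 0.75, d_between = 3,
  s_between = 0.5 — extreme heteroscedasticity) or Laplace
  (`β_i ~ Laplace(0, s_between)`; preset `sim2`: d_within = 5,
  s_within = 0.5, s_between = 0.8 — a milder regime patterned on bulk
  tumour/normal RNA-seq). No gene has exactly zero LFC;
- observations: gene-wise independent Normals, group A ~ N(0, σ²_i),
  group B ~ N(β_i, σ²_i), `n_rep` samples per group. The Normal
  observation model with a group-mean shift is the minimal model
  consistent with the moderated-t framework; baseline expression levels
  are irrelevant to the statistics and fixed at 0.

The harness draws truth and data, fits moderated statistics, applies all
seven ranking strategies, and scores (a) top-k recovery — the overlap of
the ranked top k with the true top k by |β|, k ∈ {20, 100, 500}; overlap,
not positional agreement, is what is scored — and (b) achieved FDR and FCR
of the bound-producing methods at thresholds {0, 0.5, 1, 1.5, 2}: a
discovery at threshold e (|bound| ≥ e) is false when |β| ≤ e, and a false
coverage statement when the bound's sign disagrees with β or its magnitude
exceeds |β|. Runs with no discoveries contribute a rate of 0 (the standard
FDR convention). All results are means over runs with their Monte Carlo
standard errors; everything is reproducible from a single seed.

Default problem sizes are desk-scale — 2000 genes and 20 Monte Carlo runs,
with the benchmark grid at Δ = 0.05 — chosen so the full harness runs in
seconds while leaving the Monte Carlo standard errors small against the 5%
nominal level; larger configurations (e.g. 15000 genes, 100 runs, n_rep
swept 2–128) are reachable through `preset(..., n_gene=..., n_runs=...)`.

What passing simulations do **not** show about real data: real RNA-seq has
correlated genes (the independence assumption enters the BH step),
mean-variance trends that moderation with a single prior cannot absorb,
library-size and composition effects handled upstream of this package, and
LFC distributions fatter or thinner than the two laws simulated. The FDR/
FCR guarantees are exact only under the simulated assumptions.

## Numerical choices

- Tail probabilities always go through the t survival function, never
  `1 − CDF`, so p-values near 10⁻³⁰⁰ keep relative accuracy.
- Test inversion bisects the monotone p-value function on
  `[0, |x| + 50 s]` to absolute tolerance 10⁻⁶.
- "No bound" is a distinct `NaN` result, not 0 — a confect of exactly 0 is
  a legitimate statement (sign established, magnitude not).
- A confect of 0 keeps the claimed direction in its float sign bit
  (`±0.0`); the coverage scorer reads `copysign`, not `sign`.
- Off-grid thresholds passed to `selected_set_at` round *up* to the next
  grid point: a gene is never claimed to exceed a threshold it was not
  tested at.
- BH uses the full gene universe `n_gene` as denominator even while
  scanning a surviving subset.
- The effect orientation is `mean(second group label, sorted) − mean(first)`,
  so relabelling the groups negates every effect and nothing depends on
  sample order.

## Known limitations

- Two-group designs only: no arbitrary design matrices, contrasts, paired
  designs, precision weights or count-model normalisation; feed
  pre-computed per-gene statistics for anything richer.
- The moderation step assumes a single variance prior with no covariate
  trend.
- FDR/FCR control relies on gene-wise independence of the tests.
- The grid scan's cost grows with the largest confect divided by the step;
  the `max_e` cap bounds it on degenerate near-noiseless inputs.
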