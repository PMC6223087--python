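# Methods

## The model

Bulk expression profiles are modelled as linear mixtures of a small
number of cell/tissue-type-specific profiles:

    X = S A,        X ∈ R^{n×p}_{≥0},  S ∈ R^{n×k}_{≥0},  A ∈ Δ^{k×p}

where `X` is the observed genes × samples matrix in **linear** (non-log)
units, `S` the unknown signature matrix, and each column of `A` the
mixing proportions of one sample, constrained to the probability
simplex. *Complete* deconvolution estimates both factors from `X`
alone; identifiability comes either from marker genes (genes expressed
essentially in one type only) or, when no markers are known, from gene
clusters that play the same role.

## Stage I: proportions from meta-marker profiles

Averaging the mixed profiles of type *t*'s markers gives a meta-marker
profile; stacking these yields a reduced k × p system `X̃ = S̃ A` in
which `S̃` is diagonal with unknown per-type marker levels m_t. With
d_t = 1/m_t, the per-sample sum-to-one constraint yields one linear
equation per sample, Σ_t d_t X̃[t, j] = 1, solved as non-negative least
squares whenever p ≥ k. Then A = diag(d) X̃, rescaled column-wise to
the simplex. With exclusive markers and no noise this is exact (each
meta-profile is a positive multiple of the corresponding row of A).
Stage I is scale-free per type: multiplying a meta-profile row by c > 0
is absorbed by d.

## Stage II: marker-constrained NMF refinement

`X ≈ S A` is refit by multiplicative-update NMF under the Frobenius
(RMS-residual) objective with marker rows of `S` pinned to zero in all
off-types, at initialization and after every update. Multiplicative
updates cannot revive a zero, and the mask is re-applied anyway, so the
constraint holds exactly throughout. Several seeded random restarts
are run; one restart is initialized from the Stage-I `A` (optionally
also the signature matrix derived from it), and the lowest-residual
restart wins. The sum-to-one constraint is applied to the final `A`
only — per-iteration projection would break the updates' monotone
descent, which the tests assert to 1e-9 per iteration.

Defaults: 10 replicates, max 1000 iterations, relative-change tolerance
1e-4, stabilizer eps 1e-9. The tolerance trades runtime against depth
of convergence; multiplicative updates converge linearly, so residuals
far below ~1e-4 relative require the S0-seeded start (exposed, default
off) or many more iterations.

## Signatures and standard errors

Given `A`, each gene is an independent bounded least-squares regression
of its mixed profile on the rows of `A`, with the box [lb, ub]
defaulting to the observed data range (the measurable expression
limits). Genes whose unconstrained normal-equation solution is
interior take it directly (with one iterative-refinement step); the
rest are re-solved with a trust-region bounded solver plus an
active-set polish so bound-active optima are exact. Standard errors
are the usual multiple-regression form, SE(S_ij) =
sqrt(MSE_i [(A Aᵀ)⁻¹]_jj) with MSE_i = Σ_j R_ij²/(p − k), requiring
p > k. SEs are also reported when bounds are active; they are then the
OLS approximation at the constrained solution, not an exact sampling
variance.

Note the data-range default for `ub` deliberately caps estimates at the
largest observed mixed value; genes whose true type-specific level
exceeds every mixed observation (possible when no sample is pure) are
clipped. Pass wider bounds when the measurable range is known to be
larger.

## Unsupervised mode: clustering instead of markers

Genes are partitioned by k-means or alternating ("large"-style)
k-medoids under correlation distance d(x, y) = 1 − corr(x, y),
optionally after a log2(x + offset) transform (offset default 1;
0.0001 is equally workable for sequencing data). Standardizing each
profile to zero mean and unit norm turns the k-means objective into
n − Σ_t ‖Σ_{i∈t} u_i‖, which the implementation exploits for exact,
cheap single-gene improvement moves: after the best of `replicates`
(default 500) seeded restarts converges, an online phase applies
single-gene moves until none lowers the objective. The online phase
runs on the winning restart; the returned solution therefore both
dominates every restart and is single-move optimal. Restarts that
collapse a cluster are discarded; it is an error only if all collapse.

Cluster exemplars (arithmetic mean profile for k-means; medoid or mean
for k-medoids) are always reported in linear scale and substitute for
meta-marker profiles in Stage I. For Stage II and the under-determined
estimator, the `fraction` % of genes closest to each exemplar
(correlation distance in the clustering space; default 10 %) form the
cluster subsets that carry the zero-constraints. Distance-to-exemplar
is measured in the clustering space — an assumption, since either
convention is defensible.

## Choosing k: minimum description length

The number of types is the minimizer of

    MDL(k) = −log L(X_m | θ(k)) + (k−1)p/2 · ln m + k·m/2 · ln p

over candidates k = 2..8 (default), evaluated on one fixed filtered
gene set so m is constant across candidates. The likelihood is i.i.d.
Gaussian with plugged-in variance RSS/(mp):
−log L = (mp/2)(1 + ln(2π·RSS/(mp))). The penalty counts (k−1)p free
proportions and k·m signature entries. The recommended filter before
the sweep trims 5 % of genes at each end of the expression-norm
distribution and keeps CV ≥ 0.4 — highly variable genes carry the
composition signal that separates candidate orders. Each candidate is
fit with the unsupervised S1&S2 pipeline and its signatures refit from
the final proportions before scoring. The sweep uses 20 clustering
restarts per candidate (the standalone clustering default stays at
500): on the standard mixture family (n = 2000, p = 20, k_true = 3,
5-fold markers, 10 % log-normal noise) this recovers k = 3 in 10/10
reseeded runs in ~80 s on one CPU.

## Under-determined regime (k > p)

When types outnumber samples the global system is split per type: the
marker/subset rows of type *t* form X_t ≈ w hᵀ, a rank-1 non-negative
factorization fitted by multiplicative updates (optionally h rescaled
to unit max per iteration, scale absorbed into w — the default — or a
bound-constrained UPSO search followed by box-respecting polishing).
Only the h vectors are kept, stacked, and rescaled to the per-sample
simplex. Each subsystem's scale is indeterminate (w h = (w/c)(ch)), so
within-type ratios are the meaningful output and this regime is
evaluated by per-type correlation; with exclusive markers and no noise
each X_t is exactly rank 1 and per-type correlation is 1.

## Solvers

- `nnls`: active-set non-negative least squares (Stage I default).
- `bounded_lsq`: trust-region bounded LS with active-set polish; also
  the route for the quadratic-programming formulation of the same
  problems (identical optimum — the problems are convex).
- `upso_minimize`: Unified Particle Swarm Optimization, velocity
  u·G + (1−u)·L where G and L are constriction-form updates toward the
  swarm best and the ring-neighborhood best. Defaults are the
  canonical constriction settings χ = 0.729, c1 = c2 = 2.05, u = 0.5,
  40 particles, ring radius 1, 200 iterations, with velocities clamped
  to the box width. Deterministic given the seed. On the convex
  problems here it agrees with nnls to ~1e-3 in objective; it exists
  for users who want hard space bounds inside the rank-1 scheme.

## Synthetic data

The generator draws per-gene, per-type signature levels independently
log-normal (ln-scale mean 5, sd 1 — typical linear values near 150
with about e-fold spread across types), forces each marker gene's
own-type level to ≥ fold × its largest off-type level (or zeroes the
off-type levels when exclusive), draws per-sample proportions from a
flat Dirichlet, and multiplies X = S·A by exp(N(0, σ²)) noise
(default σ = 0.1), keeping X non-negative without clipping. Standard
fixtures: "overdet" (n = 2000, k = 3, p = 20, 30 markers/type, 5-fold,
σ = 0.1), its noiseless exclusive-marker twin, "underdet" (n = 1000,
k = 4, p = 3, exclusive, noiseless), and the "mdl" family (as
"overdet", reseedable).

What the generator does not emulate: count noise/overdispersion,
library-size effects, correlated types (multicollinearity), platform
normalization artifacts, or samples missing a type entirely. Passing
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to real-data violations of
them — the known failure modes (near-identical per-sample proportions,
cohorts mixing pure and mixed samples, correlated signatures) remain.

## Numerical choices and edge cases

- Percentiles in the norm filter interpolate linearly between closest
  ranks; sd and variance use the unbiased (p − 1) denominator;
  probe-collapse ties keep the first probe in input order.
- Zero-variance genes make correlation distance undefined and raise an
  error pointing at CV pre-filtering.
- A type estimated with d_t = 0 in Stage I (infinite marker level)
  triggers a warning: that type gets zero proportion everywhere.
- RSS is floored at 1e-300 inside the MDL score to guard the log.
- All emitted proportion matrices are validated to be non-negative
  with columns summing to 1 within 1e-8.
- p = k is accepted in Stage I with a warning (exactly determined
  system); p < k routes to the under-determined estimator.

## Interface notes

The library surface is `Deconvolution(...).fit()` returning a results
object with `proportions`, `signatures` (with `se`), `rms_residual()`
and `summary()`; the `deblend` CLI wraps it with subcommands for each
pipeline step. Configuration is via command-line flags (no config-file
layer). Problem sizes in the test suite and the reproduction script
are the standard fixtures above.
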