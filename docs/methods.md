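# Methods

## Model and procedure

`stabfs` treats "which feature-selection strategy should this study use?" as
an estimation problem in its own right. A strategy is an ordered pair
(supervised filter, unsupervised filter) applied sequentially; the estimand
is a two-dimensional profile per strategy — mean held-out AUC of a ridge
classifier built on the selected features, and the stability of the selected
set under cohort perturbation — summarised by their product.

One evaluation *try* is a stratified 70/30 train/test partition drawn
without replacement. We deliberately read the resampling as subsampling
rather than with-replacement bootstrap: a with-replacement draw would place
copies of the same subject on both sides of the split and leak information
into the held-out AUC. Per class, `round(train_fraction · n_c)` subjects go
to training; both classes are guaranteed on both sides or the split raises.

Within a try, the supervised scorer ranks all *d* features on the training
subjects and keeps the top *k₁*; the unsupervised scorer then ranks **only
those k₁ columns** (training rows only) and keeps *k₂*. The rationale for
the order is functional: the supervised stage removes outcome-irrelevant
features, the unsupervised stage removes redundancy among what remains.
Selected indices are mapped back to the original feature space, so the M×d
selection matrix **Z** is always aligned to the full feature list; the final
(post-both-stages) set is what each row of **Z** records.

The classifier is ridge regression on ±1-coded labels with α = 1.0, features
z-scored by training-set statistics (test transformed with the training
parameters; training-constant features dropped with a warning). The AUC of
its continuous decision values is the Mann–Whitney statistic with midrank
tie handling.

## The stability estimator

For selection frequencies p̂_f (column means of Z) and grand mean q̄,

Stability(Z) = 1 − [ (1/d) Σ_f (M/(M−1)) p̂_f(1−p̂_f) ] / [ q̄(1−q̄) ].

The numerator is the average *unbiased* sample variance of each feature's
selection indicator; the denominator is the Bernoulli variance at the overall
selection rate. Consequences we rely on and test:

* identical rows ⇒ zero column variance ⇒ value exactly 1 (the maximum);
* under uniformly random fixed-size selection each column's unbiased variance
  estimates the Bernoulli variance, so the expected value is ≈ 0;
* the value **can be negative** for anti-correlated selections — Z =
  [[1,0],[0,1]] evaluates to −1 even though the statistic is usually
  described as ranging over [0, 1]. We return negative values unclipped:
  clipping would hide exactly the "worse than random" behaviour the decision
  graph should see.
* q̄ ∈ {0, 1} (no feature ever selected / all features always selected, e.g.
  k₂ = d) leaves the denominator zero. This raises a dedicated
  `DegenerateStabilityError` rather than returning a boundary value, and such
  combinations are excluded from the decision graph: any imputed number
  would silently distort the ranking.

## The method pool

Supervised (higher score = more class-relevant):

* **F score (S1)** — one-way ANOVA F: between-class over within-class mean
  square.
* **T score (S2)** — absolute Welch statistic |μ₁−μ₂|/√(s₁²/n₁+s₂²/n₂) with
  unbiased class variances.
* **ReliefF (S3)** — nearest-hit/miss weighting with k = 5 neighbours,
  Euclidean distance on min-max-scaled features (which also normalises the
  per-feature difference by its range). With cohorts of ~100 subjects every
  instance is used as an anchor — subsampling anchors would add a randomness
  source for no compute saving.
* **Fisher score (S4)** — Σ n_c(μ_c−μ)² / Σ n_c σ_c² with population
  (divide-by-n_c) class variances; the convention matters for small classes
  and is fixed here.

Unsupervised (higher = more preferred; orientation normalised internally):

* **Laplacian score (U1)** — Rayleigh quotient of the degree-centred feature
  on the graph Laplacian, negated so that locality-preserving features rank
  high.
* **SPEC (U2)** — alignment of the degree-weighted, normalised feature with
  the spectrum of the normalised Laplacian. Three ranking functions are
  implemented (`phi1`, `phi2`, `phi3`); the default is `phi2`, the
  trivial-eigenvector-removed form (for which a constant feature is exactly
  the worst case). `phi1`/`phi2` are negated; `phi3` is natively
  higher-is-better.
* **MCFS (U3)** — multi-cluster feature selection: embed the sample graph
  into the `n_clusters − 1` non-trivial generalised eigenvectors of
  (L, D), regress each eigenvector on the features along the LARS lasso path
  capped at `n_select_hint` active coefficients, and score each feature by
  its maximum absolute coefficient.
* **NDFS (U4)** — joint non-negative spectral clustering and ℓ2,1-regularised
  linear mapping, minimised by multiplicative updates with positive/negative
  part splitting (objective recorded per iteration and non-increasing). The
  indicator matrix F is initialised from a seeded k-means on the spectral
  embedding — a purely random initialisation frequently stalls in flat
  regions where noise features out-score planted structure. Scores are the
  ℓ2 row norms of the mapping.
* **UDFS (U5)** — ℓ2,1-regularised local discriminative analysis: a local
  scatter matrix is assembled from every sample's (k+1)-point neighbourhood
  and the orthonormal transform minimising `Tr(WᵀMW) + γ‖W‖₂,₁` is found by
  iteratively reweighted eigendecomposition. Constant features carry no
  local discriminative information; they are excluded from the optimisation
  and scored 0 (an exactly-zero column would otherwise be a free direction
  of the quadratic form and win by default).
* **Pearson score (U6)** — a redundancy filter: the negated mean absolute
  Pearson correlation of each feature with all others. Correlations
  involving a constant feature are treated as 0 with a warning.

Graph-based scorers share a symmetric kNN affinity graph (union
symmetrisation, heat-kernel weights, σ = mean kNN distance by default, which
makes the weights invariant to global feature rescaling). The ranker classes
z-score features before building the graph so no raw scale dominates the
Euclidean geometry; the low-level score functions take a caller-supplied
graph and do no preprocessing.

Two seeded `RandomRanker` baselines (ids `S0`/`U0`) are registered outside
the default pools; they provide the null reference a decision graph should
beat and are used as the degraded arm in the end-to-end tests.

## Decision graph

All pool pairings are evaluated on identical splits (split seeds depend only
on the base seed and the try index, scorer seeds additionally on the
combination name), so the comparison across combinations is paired.
Exclusions use strict inequalities — mean AUC < 0.5 or slowest try
> 1800 s — so a combination at exactly the chance level or exactly the time
ceiling is retained; degenerate-stability rows are excluded. Ranking is by
`mean AUC × stability`; everything within 1e-12 of the maximum is reported
as a co-winner (exact ties are common: two supervised filters often pick
identical top-k₁ panels on the same split, as the README example shows).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `M` | 100 | bootstrap tries per combination |
| `train_fraction` | 0.70 | training share of each split |
| `k1` | 20 | features kept by the supervised stage |
| `k2` | 10 | features kept by the unsupervised stage (final panel size) |
| `ridge_alpha` | 1.0 | L2 penalty of the classifier |
| `n_neighbors` | 5 | kNN graph / ReliefF / UDFS neighbourhood size |
| `n_clusters` | 2 | embedding dimension driver (two diagnostic groups) |
| NDFS `alpha`, `beta`, `gamma` | 1, 1, 1e8 | fit, sparsity, orthogonality weights |
| UDFS `gamma`, `local_reg` | 0.1, 1.0 | ℓ2,1 weight, local-scatter ridge |
| `max_iter`, `tol` | 100, 1e-6 | iterative solvers' stopping rule |

k₁ and k₂ are genuinely open choices — nothing in the problem fixes how many
features each stage should keep — so they are explicit configuration, with
defaults sized to a ~90-feature ROI table (keep about a fifth, then halve).
Note that k₂ = k₁ makes the unsupervised stage the identity and k₂ = d makes
stability degenerate by construction.

## Synthetic cohorts

The generator emulates the statistical shape of an ROI feature table, not
images: n = 103 subjects × d = 90 features by default (reported ROI tables
of this kind vary — e.g. 90 vs 93 regions depending on the atlas subset —
so d is a free parameter). Labels are drawn first with fixed class
counts; informative features add `effect_size × noise_sd` to the positive
class, so the standardised mean difference is exact by construction;
redundant blocks are a shared latent factor plus independent noise with
weights √r and √(1−r), giving every within-block pair a population
correlation of exactly r; everything else is i.i.d. Gaussian. Defaults: 10
informative features at effect size 1.0 (a moderate, realistic group
difference), four redundant blocks of five at r = 0.8, balanced classes.

What the generator does **not** emulate: site/scanner batch effects,
heavy-tailed or skewed intensity distributions, label noise, and spatial
autocorrelation beyond the block structure. Passing tests therefore show
that the pipeline's estimators behave as designed under their own
assumptions — not that any particular selector pair will win on real
neuroimaging data (the winner is case-dependent by design).

## Numerical choices

* Formally infinite filter scores (zero within-class variance with distinct
  means) are capped at `1e12`; globally constant features score 0 for the
  variance-ratio filters, `−4` for the Laplacian ranker (below the
  Rayleigh-quotient floor of −2), and worst-sentinel for SPEC.
* Top-k ties break to the lowest feature index (stable argsort), making
  every selection deterministic.
* All randomness derives from `numpy` `SeedSequence`s over
  (base_seed, try_index[, combination tag]); repeated runs are bit-identical
  apart from measured runtimes.
* Iterative solvers stop on relative objective change < `tol` or `max_iter`,
  returning a convergence flag and the objective trace; non-convergence
  warns but still yields scores.

## Problem sizes used in the shipped checks

The test suite and the reference script run entirely on generated data:
oracle comparisons on ≤ 6-feature fixtures, null-calibration and
planted-recovery runs at n = 200–400 subjects with M = 20–50 tries, the
full 24-combination grid at the default 103 × 90 scale with M = 50, and an
exhaustive enumeration of all 3×4 selection matrices. These sizes make every
check reproducible on a laptop-class single CPU in well under a minute each
while keeping the Monte-Carlo error of the stochastic checks far inside
their asserted bands.

## Known limitations

* Binary outcomes only; no multiclass AUC.
* The ridge penalty is fixed, not nested-tuned; the pipeline compares
  selection strategies under a common classifier, not classifiers.
* Stability is the frequency-based estimator only (no Kuncheva/Jaccard
  variants, no confidence intervals).
* SPEC's `phi2` is mathematically equivalent to the Laplacian score ranking
  on the same graph, so U1 and U2 typically agree at default settings; both
  are kept because the pool is defined method-by-method and `phi1`/`phi3`
  diverge.
* ROI extraction assumes the intensity and atlas volumes are already on the
  same voxel grid; registration, normalisation and smoothing are upstream
  concerns.
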