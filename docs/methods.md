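# Methods

## Model and estimand

The package estimates the conditional average treatment effect (CATE)
τ(x) = E[Y(1) − Y(0) | x] from tabular data (Yᵢ, Wᵢ, xᵢ) under the standard
potential-outcomes assumptions: i.i.d. sampling, consistency
(Y = W·Y(1) + (1−W)·Y(0)), unconfoundedness (Y(0), Y(1) ⫫ W | x) and overlap
(0 < e(x) < 1). Within any subgroup 𝒩 the effect is estimated by the
ratio-of-sums inverse-propensity-weighted (IPW) contrast

τ̂(𝒩) = [Σ WᵢYᵢ/eᵢ ÷ Σ Wᵢ/eᵢ] − [Σ (1−Wᵢ)Yᵢ/(1−eᵢ) ÷ Σ (1−Wᵢ)/(1−eᵢ)],

which reduces exactly to the difference of treated and control means when
e is constant. A node containing only one treatment arm has no estimate;
such nodes are never created — candidate splits whose children would lose an
arm are filtered during enumeration, and the root must contain both arms.

Propensities are taken from a known column when present (all built-in
simulations are randomized at P = 0.5), else estimated as the empirical
treated fraction (`constant`) or by unpenalized logistic regression
(`logistic`, fitted probabilities clipped to [δ, 1−δ], δ = 0.01 by default,
to bound IPW weights). Missing values are rejected at validation; there is
no imputation.

## Splitting criteria

For a candidate split of a node into left/right children (feature value ≤
threshold goes left):

- fitness (criterion `ct`): C_fit = n_L·τ̂_L² + n_R·τ̂_R², the causal-tree
  maximization surrogate for minimizing the unobservable MSE of τ̂;
- heterogeneity (`mh`): C_hete = (τ̂_L − τ̂_R)²;
- squared t-statistic (`ts`): n·(τ̂_L − τ̂_R)² / (σ̂²_L/n_L + σ̂²_R/n_R) with
  the pooled per-child variance σ̂²_child = Var(Y|W=1) + Var(Y|W=0) (sample
  variances, an arm with fewer than two samples contributes zero, the
  denominator is floored at 1e−12). Other poolings are conceivable; this
  form is the package's documented choice;
- variance reduction (`rt`, `tot`): CART impurity decrease
  SSE(parent) − SSE(left) − SSE(right) on the raw outcome (`rt`) or on the
  transformed outcome Y·(W−π)/(π(1−π)) with π the mean propensity (`tot`).
  Leaf effects are always the IPW estimate regardless of criterion.

## Multi-objective selection and the ε-archive

The `mo` criterion scores every candidate with the pair (C_fit, C_hete).
A pair s_i ε-dominates s_j when (1+ε₁)·C_fit_i ≥ C_fit_j and
(1+ε₂)·C_hete_i ≥ C_hete_j. The ε-optimal set S* satisfies two clauses:
every candidate is ε-dominated by some member, and no member is
Pareto-dominated by any candidate. S* is maintained online by discretizing
the score space into log-scale boxes of index
(⌊log C_fit / log(1+ε₁)⌋, ⌊log C_hete / log(1+ε₂)⌋): a newcomer whose box is
dominated by an occupied box is rejected; boxes dominated by the newcomer's
box are evicted; a same-box incumbent is replaced only when the newcomer
Pareto-dominates it. The replacement rule is point-level Pareto dominance by
necessity: any two positive pairs sharing a box mutually ε-dominate (boxes
are one (1+ε) factor wide), so an ε-dominance replacement test would be
vacuous and could leave a dominated representative behind, breaking the
second clause. Both clauses are verified against an O(n²) brute-force oracle
in the tests, and with ε → 0 and distinct scores the archive equals the
exact Pareto set.

Numerical choices: zero score components (log undefined) map to a reserved
sentinel box index below every real index, so zero-score candidates never
dominate and are dominated by any positive one; a 1e−9 nudge is added before
flooring so exact powers of (1+ε) land in their own box despite float log
round-off. The printed size bound 0.48/(log(1+ε₁)·log(1+ε₂)) is evaluated
with base-10 logarithms — the only base consistent (to rounding, 76.6 ≈ 75)
with the quoted example at ε = 0.2; natural logs would give 14.4.

The final split is the archive entry with maximum C_hete (`max_hete`, the
default and recommended rule; `max_fit` is available). Ties prefer the
larger other component, then the lowest feature index and threshold, then
the earliest insertion — trees are fully deterministic. Default
ε₁ = ε₂ = 0.1, inside the effective 0.05–0.2 range; larger ε coarsens the
archive and trades fitness against heterogeneity more aggressively.

## Tree construction

Growth is best-first: every expandable node is scored by its best candidate
under the configured criterion and the highest-scoring node is expanded
next, until `max_splits` internal nodes exist or no valid candidate remains.
Best-first growth makes "compare criteria at the same number of splits"
well-defined. Candidate thresholds are midpoints between consecutive
distinct sorted values; scalar criteria take a deterministic argmax (lowest
feature, then lowest threshold on ties). With `honest=True` the rows are
split 50/50 by the seeded generator: one half selects splits, the other
re-estimates every leaf effect (a leaf whose estimation half loses an arm
keeps its split-half estimate). Honest mode is off by default. Models
serialize to versioned JSON embedding the full configuration; identical
data + configuration reproduce the file byte-for-byte.

### Minimum node size

Defaults: `min_leaf = 50` samples per child and `min_arm = 2` per treatment
arm per child, both configurable. The minimum leaf size matters more here
than in ordinary regression trees: the heterogeneity score compares two
*estimated* effects, and a tiny child's IPW estimate has standard error
large enough that (τ̂_L − τ̂_R)² is maximized by noise at the smallest
allowed child. At `min_leaf = 10` the heterogeneity-driven criteria
degenerate into peeling off noise-inflated 10-sample edge children and lose
to the fitness criterion everywhere; at `min_leaf = 50` (5% of a
1000-sample study) the intended behaviour appears — heterogeneity-aware
splitting beats fitness-only splitting after the first couple of splits on
the benchmark designs. Values of this order are standard in the causal-tree
literature. For very small studies reduce `min_leaf` consciously, knowing
the heterogeneity score grows spurious.

## Synthetic designs

All designs draw covariates i.i.d. N(0,1) (the covariate law is not dictated
by the designs themselves; standard normal matches the reference designs
this benchmark family descends from, and is configurable), W ~ Bernoulli(0.5)
with the propensity recorded as a known column, noise N(0, 1) by default,
and outcome Y = m(x) + α·(2W−1)·τ(x) + σ:

| design | m(x) | τ(x) | p | α |
|---|---|---|---|---|
| 1 | x₁/2 + x₂ | x₁/2 | 2 | 0.5 |
| 2 | ½Σ₁⁴xₖ + Σ₅⁸xₖ | Σ₁⁴ 1{xₖ>0}xₖ | 20 | 1 |
| 3 | as 2 | as 2 | 58 | 1 |
| 4 | as 2 | Σ₁⁴ sin xₖ + Σ₅⁸ xₖ^{k−3} | 20 | 1 |

Designs 2 and 3 differ only in noise-covariate count (12 vs 50); design 4's
α is not dictated by its definition and defaults to 1. Under this generator
the actual CATE is E[Y(1) − Y(0) | x] = 2·α·τ(x); `SimulatedDataset` exposes
both the raw formula values (`true_tau`) and the outcome-scale effect
(`cate`), and all RMSE/wRMSE evaluation compares predictions against
`cate` — with α = 0.5 (design 1) the two coincide. What the generator does
*not* emulate about real studies: confounded treatment assignment, unknown
propensities, heavy-tailed or heteroscedastic noise, correlated covariates
and censored outcomes — passing benchmarks here demonstrates correctness of
the machinery under randomized assignment, not robustness to those features.

## Metrics and benchmark protocol

RMSE is the root mean squared error of predicted vs true effects on an
independent test draw. wRMSE down-weights squared errors by 0.1 when the
predicted and true effects share a sign and keeps weight 1 on sign
disagreements (a zero product takes 0.1 — no disagreement demonstrated),
penalizing directionally wrong calls, the costly mistake in clinical use.
`run_benchmark` draws a fresh training and test set per replicate (test size
defaults to the training size), fits every criterion at every requested
split count, and emits a tidy per-replicate table; per-cell seeds are a pure
function of (seed, design, n, rep), so adding replicates or criteria never
perturbs existing rows. The built-in checks run the comparison at n = 1000
with 20 replicates and 5 splits — deliberately modest problem sizes chosen
so the whole suite runs in minutes on one core; the same harness scales to
larger n, replicate counts and depths from the CLI.

## Known limitations

- Binary treatments and uncensored numeric outcomes only; no survival
  endpoints, matching or doubly-robust estimators.
- No pruning or cross-validated depth selection: trees are compared at a
  fixed number of splits, matching the evaluation protocol the criteria were
  designed under.
- No ensembling or confidence intervals for leaf effects.
- The heterogeneity-first selection rule (`max_hete`) targets effect
  *differences*; when heterogeneity is weak relative to noise it can spend
  splits on extreme tails while a fitness-first tree localizes the effect
  boundary better — in such regimes consider `selection_rule="max_fit"` or
  `criterion="ct"`.
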