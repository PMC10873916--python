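# Methods

This note documents the statistical procedures implemented in `netpsych`,
the defaults and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations a user
should weigh before interpreting output on real data.

## Estimation

**Input association matrix.** Ordinal items enter through Spearman (midrank)
correlations, computed complete-case. Rank correlations are invariant under
monotone transforms of each item and are the conventional robust choice for
0–3 / 0–4 Likert responses; no polychoric option is provided in this
version. Because a rank-correlation matrix need not be positive definite,
a spectral repair (eigenvalue clipping to a floor of 1e-6 with unit-diagonal
restoration, iterated to convergence) is applied before any log-determinant
is taken. Matrices that are already PD pass through untouched.

**Graphical lasso.** The precision matrix solves

    min_{K > 0}  -log det K + tr(S K) + lambda * sum_{i != j} |K_ij|

with the diagonal unpenalized, via block coordinate descent on the working
covariance with an active-set inner lasso (numba-compiled). The convention
of leaving the diagonal unpenalized matters: penalizing it changes both the
likelihood surface and model selection. Single fits default to tight
tolerances (max coefficient change 1e-7, inner 1e-9), at which the solution
matches an independent solver's objective to ~1e-15 on small problems;
path fits inside selection loops use 1e-5/1e-7, which changes selected edge
weights by < 1e-4 and never changed a selected support in our checks.
`lambda = 0` returns the unpenalized MLE `inv(S)` directly; a solve that
exhausts its sweep cap raises rather than returning a doubtful estimate.

**Model selection.** The penalty path has 100 log-spaced values from
`lambda_max` (the largest absolute off-diagonal of S, at which the network
is exactly empty) down to `lambda_max / 100`; these are the conventional
EBICglasso defaults. Per path point the Gaussian log-likelihood is
`L = (n/2)(log det K - tr(S K))` (additive constants dropped) and
`EBIC = -2L + E log n + 4 E * gamma * log p` with `gamma = 0.5` and E the
count of nonzero upper-triangle entries of the *regularized* precision (no
refit). Entries below 1e-10 in magnitude are treated as structural zeros
when counting E. Edge counts along the path are checked for monotonicity;
rare non-monotone steps are flagged on the path object, not forbidden.

**A property users should know.** With realistically strong edges
(partials ~0.2–0.4) and non-trivial density, the graphical lasso keeps
many small spurious edges at *every* penalty level that preserves the true
edges — this is the failure of the L1 support-consistency
(irrepresentability) condition under strong marginal correlations, and it
is reproduced edge-for-edge by an independent solver and even on the exact
population correlation matrix. Consequently sensitivity of edge recovery
is excellent while specificity can be poor (≈0.5 in our 15-node,
density-0.2, n=3000 benchmark), and the spurious edges are at least an
order of magnitude weaker than true ones. Interpretation of *individual
weak edges* in EBICglasso networks should be correspondingly cautious;
thresholded or refit variants, which trade sensitivity for specificity,
are deliberately out of scope here.

## Node-level inference

Expected influence is the one-step signed sum of a node's edge weights;
the bridge variant restricts the sum to edges crossing community
boundaries. Both are the one-step statistics (not two-step), matching what
centrality plots in this literature display. Global strength is the sum of
absolute edge weights over unordered pairs.

Predictability is computed as the in-sample R² of each node regressed (OLS
with intercept) on its estimated neighbors; isolated nodes score 0, and a
rank-deficient neighbor design falls back to a 1e-8 ridge and is flagged.
This is a Gaussian variant of the mixed-model nodewise approach used with
ordinal data elsewhere; exact numerical equality with mixed-model
implementations is not expected. As an independent check, the population
value implied by the generating model, `R²_j = 1 - 1/K*_jj` for the
standardized latent precision `K*`, is exported
(`implied_predictability`), and the OLS estimate matches it on latent
Gaussian draws. On discretized data, predictability is attenuated
relative to the latent value (coarse 4-level margins lose variance), so
fixture predictabilities (~0.25 mean) sit below the latent-scale values by
construction; this is a property of ordinal measurement, not an estimation
error.

## Stability

The nonparametric bootstrap resamples respondents with replacement and
re-runs the entire estimation (same gamma, same grid) per replicate;
per-edge 95% intervals are percentile (2.5/97.5, linear interpolation).
Replicates whose estimation fails are excluded and counted rather than
retried, keeping the resampling distribution honest. Bootstrapped
difference tests call an edge pair or EI pair significant when the
percentile CI of the difference excludes zero.

Case-dropping stability draws subsamples without replacement at drop
proportions {0.05, 0.10, …, 0.75} (a bootnet-style grid; B = 100 per
proportion by default), correlating each subset's expected-influence
vector with the full-sample one. Spearman correlation is the default —
rank stability is what the CS-coefficient certifies — with Pearson as an
option. CS is the largest tested proportion at which at least 95% of
subsamples correlate >= 0.7; it is non-increasing in both the threshold
and the certainty by construction. Subsets below 30 respondents are
flagged and skipped.

## Two-group comparison

The permutation test estimates both groups' networks with the identical
EBIC-glasso procedure, then permutes group labels (sizes preserved) and
re-estimates both networks per permutation — the full selection, not a
fixed-penalty shortcut (a fixed-lambda fast mode exists for
experimentation but is never the default). Statistics: S = |difference of
global strengths| and M = max absolute edge difference, computed from the
same permutation stream so the pair is jointly reproducible under one
seed (default 123). P-values use the add-one estimator
`(1 + #{perm >= obs}) / (1 + n_perm)`, valid under exchangeability and
never zero. Per-edge tests run over the family of edges nonzero in at
least one observed network — the interpretable family in practice — and
are Holm-adjusted; a permutation whose estimation fails (e.g. a constant
column after shuffling) is redrawn with a bounded retry count that is
reported. Per-edge power at realistic planted differences (0.07–0.16 on
the partial scale, n = 1500/group) is low after Holm correction; the
global S test is the sensitive instrument, which our power simulations
(rejection >= 80% at a 1.3x multiplier, n = 300/group) confirm.

## Communities

Walktrap measures node similarity by 4-step random-walk distributions over
degree-normalized absolute weights (a negative partial correlation cannot
be a transition probability; signs are retained separately for bridge
centrality) and agglomerates bottom-up; the returned partition is the
dendrogram cut maximizing Newman's weighted modularity
`Q = sum_c (e_cc - a_c²)`, with ties resolved toward fewer communities.
The merging runs through igraph's deterministic walktrap; cut selection by
our own modularity implementation is asserted optimal over every
dendrogram cut. Isolated nodes become singleton communities and are
flagged. An estimated network with no edges yields the all-singleton
partition with a warning.

## Synthetic data

The generator is the latent Gaussian threshold model. A sparse symmetric
partial-correlation matrix defines the unit-diagonal precision
`K = I - P`; if its smallest eigenvalue falls below a 0.05 margin, all
off-diagonals are rescaled by one deterministic factor — preserving the
sparsity pattern and relative weights — rather than resampled. The implied
covariance is standardized to unit variances (which leaves partial
correlations unchanged) and each latent coordinate is cut at per-node
thresholds; thresholds default to equal-probability cut-points for the
declared category count, which maximizes the information available to
rank-based estimation. Identical seeds give byte-identical tables.

Defaults define the simulated study conditions: random sparse truths use
edge weights uniform on (0.2, 0.4) — the magnitude range of strong
symptom-network partials — with within-community pairs three times as
likely to carry an edge. The 28-node study fixture mirrors the canonical
analysis layout (PHQ1-9, GAD1-7, IES1-6, four stressor nodes, SSFm/SSFr):
three scale-aligned symptom communities with chain-plus-extras structure
(within-scale partials 0.22–0.32), weak cross-scale bridges, weak
stressor→symptom edges (conflict stress to irritability at 0.10), mutually
tied support nodes with negative edges into symptoms (family support to
suicidality at -0.09), symptom items on 4 ordinal levels, stressors on 3,
support on 7 (1–7). The two-group variant multiplies group 1's nonzero
partials by 1.3 — applied on the partial scale before PD repair, matching
how the comparison test measures differences — and plants three specific
edge differences (0.07–0.16); default group sizes are 1,500 each, at which
the estimated strength ordering reliably matches the truth.

What the generator does **not** emulate: item-level marginal skew (real
symptom items are right-skewed; ours are equal-probability by default),
non-Gaussian copulas, missingness beyond optional complete-case scenarios,
measurement non-invariance between groups, and sampling designs. Passing
tests therefore certify the *statistical machinery* — solver optimality,
selection behavior, permutation validity, bootstrap behavior, community
recovery — under a clean data-generating process, not robustness to the
measurement pathologies of real surveys.

## Preprocessing conventions

Scale totals are plain sums; probable caseness is `total >= 10`. Paired
stressor domains are averaged, then (with every stressor rating) collapsed
to three levels with the boundary convention 0 → 0, (0, 2) → 1, >= 2 → 2,
preserving the "two or more is stressful" anchor for fractional merged
means. Cronbach's alpha uses the variance-ratio formula with ddof = 1.
Odds ratios use the 2x2 closed form with Wald log-scale CIs and a
continuity-corrected chi-square p; a zero cell triggers the
Haldane-Anscombe 0.5 correction, flagged in the result (an exact test is
not provided — the intended samples are large).

## Problem sizes in tests and the acceptance script

The validation suite runs at deliberately moderate scale, chosen so the
full suite completes in minutes while keeping every check informative:
permutation-test size/power use 100 replicates of 200 permutations at
n = 300 per group (p = 8); recovery benchmarks use 20 seeds at n = 3000
(p = 12–15); stability checks use B = 200 at n = 2000 (p = 10); the
acceptance script runs the full pipeline at n = 800 per group with
B = 100/50 and 200 permutations. Production analyses should use the
conventional B = 1000 bootstrap and 1000 permutations, which are the
library defaults.
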