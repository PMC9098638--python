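# Methods

## The model

`ordnet` estimates and compares *psychological networks* over ordinal
questionnaire dimensions — here, the eight 0–100 quality-of-life
dimensions of the S-QoL18 (self-esteem SEL, romantic life ROM, resilience
RES, psychological well-being PSY, physical well-being PHY, friendships
FRI, family relationships FAM, autonomy AUT), measured in multiple
diagnosis groups.

The statistical object is a Gaussian graphical model (GGM): nodes are the
observed dimensions, edges are partial correlations

    pcor_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj),

where Theta is the precision (inverse covariance) matrix. An absent edge
means conditional independence given all other nodes.

Because the observed variables are ordinal, the input correlation matrix
is **polychoric**: each variable is modelled as a discretized standard
normal latent variable, and the latent correlations are estimated by
two-step maximum likelihood — thresholds from the marginal cumulative
proportions (`threshold_k = Phi^-1(P(X <= k))`), then a bounded 1-D
likelihood maximization for each pair's rho with thresholds fixed.
Two-step estimation (rather than full joint ML) is standard practice and
orders of magnitude cheaper; the bivariate-normal rectangle probabilities
use Genz's quadrature scheme (absolute accuracy ~1e-15, far beyond the
1e-7 needed). The rho search runs over [-1 + 1e-4, 1 - 1e-4] with
tolerance 1e-6; cell probabilities are floored at 1e-12, and estimates at
the boundary (e.g. perfectly concordant tables) are clamped and flagged.
Variables with more than 15 distinct observed values (configurable) fall
back to Pearson correlation — threshold estimation becomes unstable with
that many categories, and the polychoric and Pearson estimates converge
in that limit anyway. If the assembled pairwise matrix is not positive
semidefinite it is repaired by eigenvalue clipping at zero plus
unit-diagonal rescaling, and the repair is logged.

Sparsity comes from the **graphical lasso** with **EBIC selection**: the
glasso is fitted along 100 penalty values log-spaced between
`lambda_max` (the largest off-diagonal |correlation|, at which all edges
are zero) and `0.01 * lambda_max`, and the model minimizing

    EBIC = -n (log det Theta - tr(S Theta)) + E log n + 4 E gamma log p

is selected, with `E` the number of edges, `p` the number of nodes and
`gamma = 0.5` (the conventional setting for psychological networks;
`gamma = 0` recovers BIC). The likelihood term uses `n` (not `n/2`)
scaling; only within-path differences matter, but the convention is fixed
here for cross-implementation comparison. EBIC ties break toward larger
lambda, i.e. the sparser model. Edges are declared present when
|pcor| > 1e-8 (solver zeros are exact; symmetrization can leave dust).

The glasso solver is a block coordinate descent written for this package
and compiled with numba: the resampling layers below re-fit the whole
100-value path tens of thousands of times, and warm starts across the
descending path make a full path cost ~1 ms for 8 nodes. The penalty
applies to off-diagonal precision entries only, so the working
covariance keeps `diag(W) = diag(S)`. The test suite checks the solver
against an independent implementation of the same objective
(scikit-learn's `graphical_lasso`) and against the analytic inverse at
`lambda = 0`.

## Centrality

Three indices per node: **strength** (sum of absolute incident weights),
**closeness** (reciprocal of summed shortest-path distances) and
**betweenness** (number of node pairs whose shortest path passes through
the node, with fractional credit under exactly tied path lengths — the
tie convention of Brandes' algorithm, which is what the standard
psychometrics toolchains use). Shortest paths take edge distance
`1/|w|`. Closeness of a node that cannot reach the whole network is
computed within its component and flagged; an isolated node gets
closeness 0. Only strength is surfaced in headline reports; closeness
and betweenness are computed and emitted but marked secondary, because
their case-dropping stability rarely clears the bar below.

## Accuracy and stability resampling

* **Edge CIs**: nonparametric bootstrap (default B = 1000), resampling
  subjects with replacement and re-running the entire pipeline; 95%
  percentile CIs per edge. Quantiles round outward (lower quantile by
  `method="lower"`, upper by `"higher"`), so B = 2 degenerates cleanly
  to min/max.
* **Difference tests**: for every unordered pair of edges (or node
  strengths) the percentile CI of the replicate-wise difference;
  significant iff zero falls outside. Deliberately uncorrected for
  multiple comparisons — these are descriptive accuracy checks — and the
  output headers say so. Fewer than 100 usable replicates refuses to
  test.
* **CS coefficient**: case-dropping subset bootstrap over drop
  proportions 0.05–0.75 in steps of 0.05. CS(index) is the largest
  proportion at which at least 95% of subset-vs-full Pearson
  correlations (over nodes) stay >= 0.7; an index is "stable" iff
  CS >= 0.5. Undefined correlations (zero variance on either side, e.g.
  an empty network) and failed refits count against the criterion.
  Proportions leaving fewer than 3p subjects are skipped with a notice;
  if no proportion qualifies CS is reported as 0.0 (below-minimum
  sentinel). Replicate failures are logged and excluded, with a warning
  above 10%.

## Between-group comparison (NCT)

A two-tailed permutation test per pair of groups, re-estimating both
networks on every permuted regrouping (original group sizes preserved).
Statistic families: structure (M = max |edge difference|), global
strength (|difference of the absolute edge-weight sums|), individual
edges, node strengths. p-values use the add-one convention
`p = (1 + #{perm >= obs}) / (1 + n_perm)`; two-sidedness is realized
through the absolute-value statistics. Default 1000 permutations, alpha
0.05. Holm's step-down correction is applied within each per-item family
(edges; strengths). The multi-group battery runs all pairwise
comparisons and reports **both** Holm scopes — within each comparison's
family and pooled across the 15 pairwise comparisons per family —
because the correction scope for a 6-group battery is genuinely
ambiguous; a k-group omnibus test is out of scope. The pooled sample is
canonically (lexicographically) ordered before permuting, which makes
every statistic and p-value exactly invariant to swapping the two group
labels. A permutation that fails estimation is redrawn once, then
counted as a failure and excluded from both numerator and denominator,
with a warning above 5% failures.

## Synthetic data generator

The generator inverts the analysis model, so every stage has ground
truth. A sparse precision matrix is built from a structural pattern
(chain, hub, random-sparse, or explicit) with every edge calibrated to a
common partial correlation; positive definiteness is enforced by a ridge
shift `delta = -lambda_min + 0.05` followed by re-calibration of the
off-diagonals, iterated up to 50 times to tolerance 1e-6 — this repair
preserves the zero pattern, which the structure-recovery tests depend
on. Infeasible targets (e.g. uniform pcor 0.6 on a 7-spoke hub) raise
rather than silently undershooting. Latent draws are
N(0, R) with R the unit-diagonal rescaled inverse precision, thresholded
into ordinal categories — default 5 categories at equiprobable normal
quantiles, a realistic choice for self-report instruments whose items
offer only a handful of response options; counts and cut points are
configurable, and an affine score map can place categories on the 0–100
grid. Groups (e.g. six diagnosis groups at sizes 925/212/275/133/179/225,
N = 1949) share one base network, optionally perturbed per group by
setting or rescaling named edges; each group consumes an independently
spawned substream of one seed, so adding a group never changes earlier
groups' draws, and an empty perturbation list reproduces the base group
exactly.

What the generator deliberately does **not** emulate: item-level
structure (the real instrument aggregates 18 items into 8 dimension
scores; the item weights are not public), missing data, floor/ceiling
asymmetries, or non-normal latent dependence. Passing tests therefore
demonstrate correctness of the estimation machinery under the latent
Gaussian model, not robustness of the substantive conclusions to
violations of it.

## Problem sizes used in the checked runs

The package's own acceptance checks use: polychoric recovery at
n = 5000 (50 replicates); chain-structure recovery at n = 2000
(20 replicates); NCT type-I calibration with two groups of 300 over
200 simulation runs at 100 permutations; difference-test discrimination
at n = 2000 with B = 500; stability at n = 10 000 with B = 50 subsets
per proportion; and a six-group null study replica at the group sizes
above with 300 permutations, B = 120 bootstrap and B = 40 stability
replicates. These sizes were chosen as the smallest at which the
binomial/bootstrap error bands are informative for each property.

## Known limitations

* Two-step (not joint) polychoric ML; the difference is negligible at
  the sample sizes involved but the variant is fixed.
* The glasso path is not forced to be monotone in edge count (glasso
  paths are not strictly monotone in general); only the endpoint
  property (no edges at lambda_max) is guaranteed.
* The NCT is strictly pairwise; no omnibus k-group model.
* Undirected networks only: edges carry no directional claims.
* CS coefficients are reported on the grid resolution (0.05); values
  between grid points are not interpolated.
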