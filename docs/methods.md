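# Methods

`cohortdag` implements a causal-discovery-and-validation workflow for
epidemiological cohort tables: one row per patient, a mix of continuous,
ordinal, nominal and binary features, and a single binary outcome (the
motivating use case is 30-day mortality after a first STEMI). The workflow
is: encode → discretize → learn a linear-SEM DAG by continuous
optimization → permutation-test every edge → select a weight threshold by
BIC → query the resulting graph.

## Encoding

Discrete features are mapped to integer codes. Ordinal features use their
declared real-world order (e.g. sleep duration `<6h → 0`, `6–8h → 1`,
`>8h → 2`); nominal features use the order the configuration declares, so
runs are reproducible; binary features code absence as 0 and presence as 1.
Rows with any missing or unparseable cell are removed listwise and the drop
count is reported — the downstream least-squares fit requires a complete
matrix, and imputation is out of scope. An undeclared category label is an
error rather than a drop, because it signals a mismatch between data and
specification rather than missingness.

## Supervised MDL discretization

Continuous features are binned against the binary outcome with the
Fayyad–Irani recursive entropy-partitioning procedure. Candidate cuts are
midpoints between adjacent distinct sorted values; the best cut (maximum
information gain, entropies base 2) is accepted only when

    gain > log2(n−1)/n + Δ/n,
    Δ = log2(3^k − 2) − [k·Ent(S) − k1·Ent(S1) − k2·Ent(S2)],

and accepted cuts recurse independently into both sides. Bins are
left-closed/right-open at each cut. The outcome supervises every feature —
it is the study's class label throughout. Features for which no cut clears
the criterion collapse to a constant column; constant columns are
uninformative and destabilise the least-squares fit, so they are excluded
from structure learning with a logged warning. The partition depends only
on the ordering of values, so any strictly increasing transform of a
feature leaves every record's bin unchanged (a property test enforces
this).

## Structure learning

The model is the linear SEM `X = XW + Z`, with `W[i, j]` the weight of the
edge `i → j` (parents index rows, children columns). Integer codes from
discretization are treated as real numbers, and each column is centered
(the model has no intercept); optional unit-variance scaling is off by
default. Acyclicity is the smooth constraint
`h(W) = trace(e^{W∘W}) − d = 0`, and the fit solves

    min_W ‖X − XW‖²_F/(2n) + λ1‖W‖₁   s.t.  h(W) = 0

by an augmented Lagrangian: minimise
`loss + λ1‖W‖₁ + α·h + (ρ/2)h²` over `W`, escalate `ρ` tenfold whenever
`h` fails to shrink by a factor 4, and update `α ← α + ρh`, stopping at
`h ≤ 1e−8` or at the penalty cap `ρ = 1e16`. `λ1` defaults to 0, matching
the plain least-squares objective; it is exposed because sparsity
regularisation is common in practice. Initialisation is `W = 0`,
deterministic. Hard-thresholding of small weights is deliberately a
separate stage (model selection), not part of the fit.

The smooth subproblem is solved by an own L-BFGS (two-loop recursion,
memory 10, Armijo backtracking) compiled with numba, with the loss
evaluated through the d×d Gram matrix so the cost per iteration is
independent of n, and the matrix exponential computed by
scaling-and-squaring. This kernel exists because the permutation stage
refits the structure thousands of times; the test suite verifies it against
scipy's L-BFGS-B on the identical objective (agreement to ~1e−3 on fitted
weights, far below sampling noise) and verifies both analytic gradients
against central finite differences. Inner tolerances default to
`gtol = 1e−5` (gradient infinity norm) and `ftol = 1e−8` (relative
objective change); loosening them further starts to move fitted weights at
the 1e−2 level, tightening them is indistinguishable in the tests. With
`λ1 > 0` the subproblem runs on the smooth nonnegative splitting
`W = W⁺ − W⁻` under scipy's bound-constrained L-BFGS-B.

A note on edge direction: the adjacency convention is fixed by the model
equation `X = XW + Z` (row = parent). For a dependent pair whose variances
differ — e.g. a continuous covariate and a low-prevalence binary outcome —
the unregularised least-squares objective often orients the edge from the
lower-variance node, so a planted covariate→outcome effect may surface as
outcome→covariate. Detection-style analyses should therefore consider both
orientations of a pair (the power experiment below does).

## Permutation validation

Each entry of the observed adjacency gets a two-sided add-one permutation
p-value

    p_ij = (1 + #{b : |W_b[i,j]| ≥ |W_obs[i,j]|}) / (B + 1),

where `W_b` is refit on a dataset whose outcome column has been uniformly
permuted (the multiset of labels, hence the outcome prevalence, is
preserved exactly). The add-one form guarantees `p > 0` and finite-B
validity: under the null the rejection probability at level α is at most α.
Permutation b uses seed `master_seed + b`, so p-values are independent of
execution order and reproducible. Edges with `p > α` (default 0.05, no
multiplicity correction) are pruned by zeroing; pruning precedes weight
thresholding. Permutation fits that fail to converge are excluded and the
effective B is reported.

Two design points deserve emphasis:

- **MDLP cuts are frozen before permuting.** The cut points learned on the
  original data are reused for every permuted replicate. MDLP is supervised
  by the very labels being shuffled; re-learning cuts under shuffled labels
  almost always yields no cuts at all and destroys the fit.
- **Outcome-only shuffling has degenerate covariate–covariate nulls.**
  Shuffling only the outcome leaves all other columns untouched, so
  permuted weights for covariate–covariate edges sit essentially at their
  observed values and their p-values are near 1; taken literally, the
  procedure prunes every such edge. `null_mode="outcome_shuffle"` is the
  default because it reproduces the published procedure and gives exactly
  exchangeable (valid) nulls for outcome-incident edges;
  `null_mode="full_shuffle"` (every column permuted independently) is
  provided for whole-graph questions such as the recovery experiments.

The default `B = 200` is a desk-scale setting; the shipped paper profile
uses `B = 100,000` and `α = 0.05` (runtime is linear in B).

## Threshold selection

Candidate thresholds `t` (default grid 0.00–0.50 step 0.01) zero all
entries with `|W| < t`. In the rare case that a thresholded support still
contains a cycle, the weakest edge on each remaining cycle is removed and
logged. Each structure is scored on the discrete data with the
decomposable BIC (natural logarithm; the data are discrete at this point by
construction):

    score(G; D) = Σ_i [ LL_i − (ln N / 2)·(r_i − 1)·Π_{p∈pa(i)} r_p ],

with `LL_i` the maximized multinomial log-likelihood of node i given its
parent configurations (`0·log 0 = 0`) and `r` the level counts taken from
the feature specifications. The selected threshold is the elbow of the
(threshold, BIC) curve: after min–max normalizing both axes, the grid point
of maximum perpendicular distance to the chord joining the curve's
endpoints, with ties (including the degenerate exactly-linear curve)
resolved toward the smaller threshold. The reference threshold from the
motivating study, 0.1, ships as `REFERENCE_THRESHOLD` and is the fallback
when no curve is computed.

## Graph queries

The final adjacency becomes a `networkx` DAG (edge per nonzero entry,
row→column direction). A variable is classified relative to an
exposure/outcome pair as a **mediator** when it lies on a directed path
exposure → … → outcome, as a **confounder** when it is an ancestor of both
exposure and outcome and not a mediator (the common-ancestor
operationalisation of "associated with both but not an intermediary"), and
as neither otherwise. Simple-path enumeration is capped (default 10,000)
with an explicit truncation flag. Directions are reported as learned;
Markov-equivalence caveats are left to the user.

## Group statistics

Baseline-table machinery: Welch's unequal-variance t-test for continuous
features — computable from printed (mean, SD, n) summaries alone — and
Pearson chi-square without continuity correction for categorical features,
globally over all levels and per level against the rest, with no
multiplicity adjustment. Welch is used because it reproduces the printed
summary-table p-values the package's tests re-derive (e.g. the
triglycerides row gives 0.0433); where a source prints mutually
inconsistent values for the same row, the package keeps this single
convention rather than matching each print. Levels with zero count in both
groups are reported as not applicable.

## Synthetic registry generator

Cohorts are drawn from a known linear SEM: nodes in topological order,
`value = Σ w·parent + N(0, σ²)` with σ = 1 by default, discrete nodes
emitted by thresholding their latent at fixed cut points. Cut points are
quantiles estimated from a separate calibration draw of the same SEM
(derived seed, n = 20,000) rather than from the generated sample itself,
for two reasons: rows of a cohort stay i.i.d. (the exchangeability the
permutation test's validity argument needs), and marginal frequencies —
including the outcome prevalence — are hit in expectation with binomial
sampling variation, as a real registry's would be.

The default registry-like SEM has 28 nodes: 27 epidemiological features
named after the usual STEMI-registry variables (six continuous laboratory
and age measurements, the rest categorical with marginals near the
registry's printed ones) plus a binary 30-day-mortality outcome binarised
at the 92.3% quantile of its latent (7.7% prevalence). It embeds the
pathway structure the graph queries are designed for: the mediation chain
sex → alcohol → hypertension → mortality alongside a direct
sex → mortality edge, and socioeconomic status as a common-ancestor
confounder of physical activity and mortality. Weights (0.3–1.0) are set
so pathway signals are recoverable at registry scale without dominating
the table.

What the generator does **not** emulate: real registries have missing
data, measurement error, nonlinear and interaction effects, and discrete
variables whose dependence structure is not a thresholded Gaussian.
Passing recovery tests on this generator shows the pipeline recovers the
structure class it assumes (linear, acyclic, complete-case); it is not
evidence about any real registry.

## Experiment sizes and operating characteristics

The bundled experiments (test suite and `scripts/acceptance.py`) use these
problem sizes, chosen as the smallest that give stable Monte-Carlo
estimates:

- Acyclicity oracle: 1,000 random matrices, d ≤ 6, weights ±[0.5, 1.5].
- Structure recovery: 6-node all-continuous SEMs, 6 edges, |w| ∈ [1, 2],
  n = 2,000, 10 seeds, fixed threshold 0.1, no permutation stage (an
  all-continuous SEM has no binary class variable for MDLP or the
  outcome-shuffle null).
- Null validity: 5 independent continuous covariates, outcome independent
  at 7.7% prevalence, n = 300, B = 200, 100 replicates; the rejection rate
  of the 10 outcome-incident entries at α = 0.05 is compared with 0.05 ±
  3·SE, SE computed at N = 1,000 decisions. Decisions within a replicate
  share data and permutations, so they are not fully independent; with
  i.i.d. covariates the dependence is mild and the band held comfortably
  in development runs (~0.05–0.06).
- Power: one planted covariate→outcome link (latent weight 1.0, outcome at
  50% prevalence), n = 500, B = 200, 50 replicates; detection counts
  either orientation of the pair (see the edge-direction note above).
- Registry pipeline: n = 3,192 cohort, B = 200, elbow-selected threshold.

## Known limitations

- Unregularised least squares orients low-variance nodes (e.g. rare binary
  outcomes) as parents more often than not; interpret single-edge
  directions cautiously and prefer pair-level statements.
- Outcome-only shuffling cannot validate covariate–covariate edges (their
  null is degenerate); `full_shuffle` tests exchangeability against full
  independence instead, which is a different and stricter null.
- BIC scoring requires fully discrete data; all-continuous analyses must
  use a fixed threshold.
- The elbow rule is a deterministic heuristic; on nearly linear BIC curves
  the tie-break (smallest threshold) governs, and users who want the
  published setting can pass the fixed threshold 0.1.
- MDLP with a rare outcome is conservative: features only weakly related
  to the outcome often receive no cut and are excluded; this mirrors the
  information actually available for supervised binning at that prevalence.
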