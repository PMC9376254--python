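# Methods

`netpsych` implements the regularized partial-correlation ("symptom
network") analysis workflow used to study how the three alexithymia
factors of the TAS-20 relate to the nine cognitive emotion-regulation
strategies of the CERQ in internet-addicted students. This note documents
the statistical model, the conventions and defaults, and what the
synthetic-data generator does and does not emulate.

## Model

The 12 analysis variables (TAS-20: DIF, DDF, EOTS; CERQ: Slb, Acc, Rum,
Pstvrf, Rop, Pstvrp, Pip, Cts, Blo) are treated as jointly Gaussian after
subscale summation. The network is the Gaussian graphical model: edge
weights are regularized partial correlations

    w_ij = -K_ij / sqrt(K_ii K_jj),

where K is the precision matrix estimated by the graphical lasso, i.e.
the maximizer of

    log det K - tr(S K) - lambda * sum_{i != j} |K_ij|,

with S the Pearson (optionally Spearman) correlation matrix of the
screened sample. The diagonal is unpenalized. Zero off-diagonal entries
of K are exactly absent edges.

### Penalty selection

`lambda` is selected on a descending log-spaced grid of 100 values from
`lambda_max` (the smallest penalty that empties the graph, i.e. the
largest absolute off-diagonal correlation) down to `0.01 * lambda_max`,
by minimizing the extended Bayesian information criterion

    EBIC = n (tr(S K) - log det K - p) + |E| log n + 4 |E| gamma log p,

with `gamma = 0.5` by default and |E| the number of nonzero
upper-triangular entries. The likelihood term is written as the deviance
against the saturated fit, so a fully saturated model on its own data
scores 0; the constant offset does not affect selection. EBIC ties are
broken toward the larger (sparser) lambda.

### Solver

The solver is a block coordinate-descent graphical lasso (one lasso
sub-problem per column), numba-compiled and warm-started along the lambda
path, which makes the thousands of refits needed by the case-dropping
bootstrap cheap (~15 ms for a full 100-lambda path at p = 12). Outer
sweeps run until the working covariance stabilizes; convergence is then
certified on the returned estimate itself via the KKT stationarity
residual (`K^-1 = S + lambda * sign(K)` off-diagonally, within 1e-6) and
the duality gap (`tr(S K) - p + lambda ||K||_1,off` within 1e-7), with an
iteration cap of 10,000 sweeps. Certifying on the estimate matters: the
working dual point can look converged a full sweep before the precision
matrix actually is. The test suite checks the solver against an
exhaustive sign-pattern enumeration oracle on 3-node problems (1e-4) and
against scikit-learn's implementation on 12-node problems.

Non-positive-semidefinite correlation inputs (possible after listwise
deletion quirks) are repaired by eigenvalue flooring at 1e-8 followed by
rescaling to unit diagonal, with a logged warning.

A note on sparsity along the path: the glasso support is *not* exactly
nested in lambda; isolated single-edge drops as lambda decreases are
genuine solver behavior, so the "edge count grows as lambda shrinks"
property is asserted as a trend, not entrywise.

## Questionnaire scoring and screening

* IAT: total = sum of 20 items (range 20-100); inclusion requires total
  strictly greater than 50.
* TAS-20: reverse-keyed items are transformed `x -> 6 - x` before
  summation. The shipped default key is the published one (DIF 7 items:
  1,3,6,7,9,13,14; DDF 5: 2,4,11,12,17; EOTS 8: 5,8,10,15,16,18,19,20;
  reverse: 4,5,10,18,19) and is fully overridable via config, since
  translated versions of the instrument can differ.
* CERQ: nine 4-item subscales; the default key maps consecutive blocks
  of four items in canonical subscale order, also overridable.
* Missing data: rows with any missing or out-of-range item are flagged
  and removed listwise, never imputed; participants absent from any
  instrument are excluded with a warning.

## Centrality

* Strength: sum of **absolute** edge weights at a node. The absolute
  convention is standard for signed psychometric networks and is what
  reproduces the published ranking; the signed sum (one-step expected
  influence) is exposed separately via `strength(net, signed=True)`.
* Distances: edge length `1/|w|` by default (stronger association =
  shorter path); `-log|w|` is available via the `transform` argument.
* Closeness: `(p-1) / sum_j d_ij`; defined as 0 whenever any other node
  is unreachable.
* Betweenness: Brandes algorithm with fractional counting of tied
  shortest paths (deterministic under exact ties); unreachable pairs
  contribute nothing.

Because the distance transform and tie conventions are not universal,
raw closeness/betweenness values are only comparable between
implementations up to ranking; strength and edge weights compare
directly.

## Bridge expected influence

For node i in community C (communities are fixed by instrument
membership: 3 TAS vs 9 CERQ nodes), the 1-step BEI is the sum of edge
weights to nodes outside C. Both variants are reported:

* `bei_signed` — the textbook definition;
* `bei_absolute` — sum of absolute cross-community weights.

On the bundled reference network the two disagree: EOTS carries two
negative cross-community edges (to Pstvrp and Rum), so its signed BEI is
-0.03 while DIF's is +0.25, yet its absolute BEI (0.61) dominates. The
published bridge-node pair (EOTS and Cts) is reproducible only under
absolute summation, which is therefore the display default; the
ambiguity is deliberate and surfaced rather than resolved silently. Ties
are broken by canonical node order with a logged warning.

## Predictability

Node predictability is the nodewise R² from regressing each subscale on
the other eleven — for all-continuous data this OLS form is the Gaussian
special case of the nodewise mixed-model approach; an L1-regularized
nodewise variant tuned by EBIC (`method="lasso_ebic"`) is provided for
comparison. R² is clipped to [0, 1] against numerical noise. Exactly
duplicated (or negated) column pairs raise an error naming the columns;
more diffuse rank deficiency is tolerated through least squares, so a
column that is an exact linear combination of others scores R² = 1. For
Gaussian data with precision K the population value is
`1 - 1/(K_ii * Sigma_ii)`, which the sample estimate provably approaches;
the tests verify recovery within 0.01 at n = 100,000.

## Stability

The case-dropping bootstrap drops `floor(q n)` participants uniformly
without replacement for each proportion q in {0.05, 0.10, ..., 0.75}
(the conventional grid whose 0.75 ceiling caps the CS coefficient),
re-estimates the network, and correlates each replicate's centrality
vector with the full-sample one. The CS coefficient is the largest q at
which at least 95% of replicates correlate >= 0.7; CS >= 0.5 is the
conventional sufficiency threshold. Each grid proportion qualifies
independently and the largest qualifying one is reported even if the
qualifying set is non-contiguous. Zero-variance or failed replicates are
recorded as missing and excluded from the quantile, never coerced.
Replicate RNG substreams are spawned deterministically from the master
seed, so results are independent of execution order. B = 1,000
replicates per proportion is the study-scale default; desk-scale runs
(tests, the acceptance script) use B = 250, which already decides the
ceiling question.

## Synthetic data

The generator produces, with full determinism per seed:

* sparse two-community precision matrices with planted cross-community
  (bridge) edges, made positive definite by diagonal dominance (diagonal
  = 1.05 x row sum of absolute off-diagonals, floored at 1). Ground
  truth is defined at the partial-correlation scale — exactly what the
  estimator targets — so recovery checks are direct;
* multivariate-normal subscale scores from any such precision matrix;
* 5-level Likert discretization at standard-normal equal-probability
  quantiles (or user thresholds);
* item-level responses (`item = loading * z + sqrt(1 - loading^2) *
  noise`, discretized), with TAS reverse-keyed items emitted pre-reversed
  so standard scoring recovers the factors; default loading 0.85, a
  typical subscale-internal-consistency regime;
* a study cohort with the survey's composition: 1,677 participants of
  whom exactly 560 have IAT totals above 50. The composition is a design
  parameter (rejection sampling per group), mirroring a survey that
  reports a fixed screened count; the screened subgroup's latent subscale
  scores follow the bundled reference network's Gaussian graphical
  model, the remainder the same topology at half strength.

What the generator does **not** emulate: item-level floor/ceiling
effects and skew of real Likert data, non-Gaussian dependence (copulas),
missingness mechanisms, and — critically — the full covariance of the
original raw data. The bundled reference network is the *published
regularized* network: its weights are L1-shrunken and sparsified, so the
population it defines explains less nodewise variance (average R² about
0.47) than the raw survey data did (reported 0.63). Passing tests
therefore demonstrate pipeline correctness and estimator consistency
against a known ground truth, not agreement with every statistic of the
unavailable raw dataset.

## Reference fixture

The bundled 12-node weight table stores the published edge weights; the
source table prints magnitudes only, and the two edges reported negative
in the accompanying text (EOTS-Pstvrp = -0.18, EOTS-Rum = -0.14) are
stored signed. With these signs the matrix I - W is positive definite
(minimum eigenvalue 0.108), which is what allows it to double as a
generating precision matrix.

## Problem sizes used by tests and the acceptance script

Chosen so the full suite and the script each run in a few minutes on one
core: screening at the survey scale (n = 1,677); edge-weight and
predictability recovery at n = 100,000 (sampling error ~0.004, well
below the 0.01 print precision of the reference weights); stability at
the screened n = 560 with B = 250; parameter-recovery sweeps at n = 5,000
over 50 seeds.

## Known limitations

* Continuous-Gaussian treatment of ordinal subscale sums (the field's
  default; polychoric/nonparanormal inputs are out of scope).
* No network-comparison tests, no edge-weight difference bootstraps, no
  2-step bridge indices, no data-driven community detection.
* Raw closeness/betweenness values depend on the distance-transform
  convention; only rankings are implementation-portable.
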