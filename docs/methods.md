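# Methods

## Model and observables

The dichotomous Rasch model places persons and items on one logit scale:
logit P(X_ij = 1) = θ_i − b_j. Its defining consequence for this package
is additivity: the log-odds is a non-interacting sum of a person effect
and an item effect, which is the structure additive conjoint measurement
(ACM) axiomatizes. Under the Rasch model the person sum score is
sufficient for θ and the item total for b, so the observable summary
table — rows indexed by sum score s, columns by items sorted by marginal
proportion correct, cells holding p(s, j), the fraction of score-s
examinees answering item j correctly — orders persons and items exactly
as the latent parameters would. The cancellation axioms can therefore be
checked on this table before any scale is constructed.

Persons with zero or perfect scores are excluded from the table (their
rows are deterministic); column order ties are broken by original item
index so the table is reproducible.

## The conjoint check

A check operates on a 3-matrix: three score rows and three item columns
drawn uniformly at random from the table (rows and columns kept in table
order). The axioms constrain the nine true proportions π:

* single cancellation: π nondecreasing down each column and across each
  row;
* double cancellation, both orientations: if π(2,1) ≥ π(1,2) and
  π(3,2) ≥ π(2,3) then π(3,1) ≥ π(1,3); if π(1,2) ≥ π(2,1) and
  π(2,3) ≥ π(3,2) then π(1,3) ≥ π(3,1).

All inequalities are weak: ties satisfy the axioms, so the feasible
region always contains every constant matrix — which also makes the
sampler's constant-matrix initialization feasible by construction.

A note on the classical form of double cancellation: given antecedents
comparing (2,1) vs (1,2) and (3,2) vs (2,3), the implied conclusion
compares the corners (3,1) and (1,3). Worked presentations of 3-matrix
checks sometimes state the conclusion as a comparison between an
anti-diagonal cell and the top-right cell instead; the deterministic
checker here (`ordinal_axiom_check`) implements the classical Luce–Tukey
corner conclusion, under which the standard worked 3-matrix
(0.22/0.61/0.70, 0.36/0.72/0.76, 0.45/0.69/0.81) shows exactly one
single-cancellation reversal and no double-cancellation violation.

### Constrained posterior and sampler

Each 3-matrix gets the posterior over π ∈ [0,1]^9 with independent
likelihoods y(r,c) ~ Binomial(n_r, π(r,c)) and a uniform prior truncated
to the axiom region. The sampler is single-site Metropolis–Hastings with
independence proposals: cell (r,c)'s proposal is its unconstrained
posterior Beta(y+1, n−y+1). Because the truncated target is exactly that
product of Betas times the feasibility indicator, the acceptance
probability reduces to the indicator that the proposed matrix satisfies
the constraints — the sampler is exact and has no tuning parameters.
Defaults: 500 burn-in sweeps, 2000 kept sweeps, one chain per 3-matrix.
Chains for all sampled 3-matrices run vectorized in lockstep (fixed
blocks of 512 matrices; kept draws held in float32), so a full run at
m = 5000 matrices stays within ordinary memory. A chain that accepts no
proposal after burn-in (possible only for pathological inputs) raises
with diagnostics rather than returning a degenerate interval.

### Violation rule

A cell is flagged when its empirical value lies outside the equal-tailed
credible interval (default level 0.95) of its constrained posterior. The
empirical value is the add-one smoothed proportion (y+1)/(n+2), the
posterior mean of the cell under the same uniform prior — not the raw
y/n. The distinction only matters at the boundary, but there it is
decisive: a raw proportion of exactly 0 or 1 lies outside *any* interval
built from continuous posterior draws, so the raw rule would flag every
all-correct or all-incorrect cell unconditionally. Such cells are common
in small score groups and at wide difficulty spreads, and flagging them
regardless of the constraints inflates the violation rate and distorts
its dependence on design (wide-difficulty tests would look *worse* than
narrow ones when the opposite holds). With the smoothed value, a
boundary cell is flagged exactly when the order constraints genuinely
pull its posterior away from what was observed. Alternative rules were
evaluated and rejected: exempting boundary cells entirely discards real
signal on long tests, and posterior-predictive intervals are far too
conservative (violation rates collapse to ~0 under every design).

### Aggregation

The headline statistic aggregates over all nine cells of each of m
sampled 3-matrices (m = 5000 by default): the unweighted proportion is
the plain mean of the violation flags over cells, and the weighted
proportion — the statistic used everywhere downstream — weights each
cell by the number of examinees in its score row. The unweighted mean is
computed at the cell level; averaging within items first and then across
items would be a near-equivalent alternative but is not used.
3-matrices are drawn with replacement across draws, so m is independent
of table size; a degenerate table with exactly 3 rows and columns simply
yields m copies of the unique 3-matrix.

## Rasch estimation

Item difficulties are estimated by conditional maximum likelihood (CML):
conditioning on sum scores removes θ entirely, and the conditional
likelihood's normalizing constants are the elementary symmetric
functions (ESFs) γ_s of the easiness parameters ε_j = exp(−b_j),
computed by the standard summation recursion (stable for positive
inputs). Newton–Raphson on the conditional log-likelihood uses exact
ESF-based gradients and the exact information matrix (leave-one-out and
leave-two-out ESFs are recomputed directly rather than by the
subtraction recurrence, trading a factor of J in work for numerical
safety). Identification is by the sum-zero constraint on difficulties;
convergence is declared at gradient norm < 1e-8, with at most 100
iterations and damped early steps. Items with no variance among
interior-score persons abort with an error naming the item — silently
dropping them would change the table geometry downstream.

Person abilities are ML given the fixed difficulties; since the estimate
depends on data only through the sum score, the score-to-ability map is
solved once (vectorized Newton on the score equation) and persons are
mapped through it. Zero and perfect scores, whose ML estimates are
infinite, receive finite values by monotone cubic (PCHIP) extrapolation
of the interior (s, θ̂_s) curve, with a linear-extension fallback that
guarantees the map stays strictly increasing. The exact extrapolation
recipe only affects bootstrap replicate persons with extreme scores and
has no measurable effect on the null distribution.

Infit and outfit are the usual information-weighted and unweighted
mean-square residual statistics with extreme-score persons excluded;
both have expectation 1 under the model.

## Bootstrap null and decision

Given a dataset, the null distribution is built by fitting the Rasch
model (CML + the score-to-ability map), forming P̂_ij =
logistic(θ̂_i − b̂_j) for the actual examinees — each keeps their own
estimated ability, rather than drawing from a smoothed ability
distribution — and simulating B independent datasets of Bernoulli
responses with unit discrimination (always, regardless of how the data
arose: the null embodies the Rasch hypothesis). Each replicate gets the
same conjoint check, and the observed statistic's percentile is
100 · #(null ≤ stat)/B, ties counting toward the percentile
(conservative for rejection). Rejection thresholds are the 90th, 95th
and 99th percentiles; the 95th is the default. Replicates whose check
fails (e.g. a resimulated dataset with too few score groups) are dropped
with a logged count rather than retried.

Defaults B = 100 and m = 5000 match the full-scale procedure; all scale
knobs are arguments.

## Synthetic data generator

`datagen` draws θ ~ N(mean, sd²) (default N(0,1)), difficulties
~ N(diff_mean, scale) with an explicit flag saying whether the printed
scale is a variance or an SD — published difficulty distributions appear
in both parameterizations, and the two reference spreads used throughout
(0.25 "narrow", 1.44 "wide") are variances. Discriminations are all 1
("rasch") or i.i.d. uniform; the non-Rasch generator is the standard
two-parameter logistic, logit P = a_j(θ_i − b_j). The study designs use
U(0.8, 1.2) ("narrow") and U(0.5, 1.7) ("wide"). The real-data-like
sensitivity design (N = 1000, J = 24, b ~ N(−0.04, 0.34),
θ ~ N(−0.18, 0.90)) is interpreted on the variance scale for
consistency with the other printed spreads; the flag lets a user choose
otherwise.

What the generator does not emulate: guessing (3PL lower asymptotes),
asymmetric response functions, multidimensional θ, missing data, local
dependence. Passing checks on simulated 2PL violations therefore show
sensitivity to unequal discrimination specifically, not to every way
real data can depart from interval scalability.

## Distribution-overlap metrics

Study summaries compare a non-Rasch condition's violation proportions
with its matched Rasch condition via the pooled-SD standardized mean
difference (sign convention: non-Rasch minus Rasch) and the overlapping
index η = ∫ min(f̂_x, f̂_y): Gaussian kernels, normal-reference bandwidth
1.06 s n^(−1/5), a 1024-point grid spanning the pooled range padded by
three bandwidths, clipped to [0,1]. η is estimator-dependent in its
second decimal; any comparison against externally computed values should
allow for that.

## Reproducibility and problem sizes

Every public operation takes a seed; one master `SeedSequence` spawns
independent child streams per replication, so results are identical
regardless of evaluation order and parallel runs stay reproducible.
Identical inputs, seeds and configuration give bit-identical outputs.

The test suite and the acceptance script run reduced-scale replicas of
the full study designs: condition means use 20 replications with m = 500
3-matrices and chains of 300 burn-in/600 kept sweeps; bootstrap-based
checks use 10 outer replications × 40 bootstrap replicates with m = 600
and chains of 200/400. At these sizes the Monte-Carlo standard error of
a condition mean is ≈ 0.002, well inside the comparison tolerances; the
bootstrap settings keep enough resolution (percentile granularity 2.5,
statistic SD ≈ 0.004) for the power checks to be meaningful, which
m ≈ 300 does not.

## Known limitations

* The violation proportion is a diagnostic, not an effect size: its
  null level moves with N, J and difficulty spread, which is exactly why
  the bootstrap calibration exists.
* At N = 250 the procedure has little power against even wide
  discrimination spreads; a sensitivity simulation
  (`sensitivity_check`) at one's own design is the intended guard
  before interpreting a non-rejection.
* The bootstrap resimulates from point estimates; estimation error in
  θ̂ mildly inflates the null spread, and no shrinkage correction is
  applied.
* Single and double cancellation are necessary, not sufficient, for
  ACM; higher-order cancellation, solvability and Archimedean conditions
  are untestable with finite dichotomous data and are not addressed.
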