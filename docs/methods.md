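# Methods

## The problem

When a binary risk prediction model is validated in an external sample, its
ROC curve usually moves.  Two very different things move it: a different
*case mix* (the distribution of predicted risks in the new population) and
genuine *miscalibration* (predicted risks that no longer match observed
event fractions).  An AUC drop alone cannot distinguish them.  The package
implements the model-based ROC (mROC) framework, which separates the two,
and a Monte-Carlo *unified test* of moderate calibration built on it.

Throughout, `pi*_i` is the model's predicted risk for subject `i`,
`Y_i ∈ {0,1}` the observed outcome, and *moderate calibration* means
`P(Y = 1 | pi* = p) = p` for every attained `p`.

## Curves

**Empirical ROC.**  With `F1n`/`F0n` the empirical CDFs of predicted risk
among events/non-events, the curve traces
`(1 − F0n(t), 1 − F1n(t))` over thresholds `t`.

**mROC.**  Replace the observed outcomes by their model-implied law
`Y* ~ Bernoulli(pi*_i)`.  By Bayes' rule the case and control CDFs become
weighted eCDFs of the risks with weights `pi_i / Σ pi` and
`(1 − pi_i) / Σ(1 − pi)`.  The mROC is the ROC curve of these weighted
distributions: the curve the model *should* produce in this sample if it
were calibrated here.  It depends on the risks only — outcomes never enter
— so it automatically carries the validation sample's case mix.  Its area
(mAUC) equals the model-based c-statistic; the package computes that
c-statistic independently as a ratio of pairwise weights
(`Σ_{ij} pi_i(1−pi_j)[I(pi_i>pi_j) + ½·I(pi_i=pi_j)] / (Σpi · Σ(1−pi))`,
all ordered pairs) and tests the identity to 1e-10.  The tie terms —
including the `i = j` diagonal — are what make the identity exact at finite
`n`; the tie-free form some references use agrees only asymptotically.

**Representation.**  Curves are vertex lists with linear interpolation.
Tied risks collapse to a single vertex, so a tie group spanning both
classes appears as a diagonal segment; the all-tied curve is then exactly
the chance line, and the trapezoid area equals the tie-corrected
Mann-Whitney statistic.  We deliberately avoid dense grids: every area and
every curve difference below is evaluated in closed form on the vertex
lists, with zero discretisation error.

**Curve differences.**  `∫ |c1(t) − c2(t)| dt` is computed on the union of
the two curves' fpr breakpoints.  Inside each union segment both curves are
linear, so the absolute difference integrates exactly once the segment is
split at a sign change of the difference (one linear equation per
crossing).  Endpoint limits are recovered by evaluating each curve's
covering linear piece, which sidesteps the ambiguity of curve "values" at
vertical risers — risers have zero width and cannot contribute to an
integral in `t`.  The implementation is validated against a 10^6-point
midpoint Riemann oracle (agreement to 1e-6) and satisfies symmetry and the
triangle inequality exactly.

## The unified calibration test

Moderate calibration is equivalent to the conjunction of

* H0A, mean calibration: `E(pi*) = E(Y)`, tested with
  `An = |Σ(Y_i − pi_i)| / n`;
* H0B, ROC/mROC equality, tested with
  `Bn = ∫ |ROCn(t) − mROCn(t)| dt`.

**Null simulation.**  Under the null the outcome law *is*
`Y* ~ Bernoulli(pi*_i)`, so the joint null distribution of `(An, Bn)` is
simulated directly: redraw outcome vectors against the fixed risks, M times
(default M = 10^5; the power studies use 2,000).  The mROC and the
tie-group layout are computed once per test.  Draws in which all simulated
outcomes coincide leave the ROC undefined; they are redrawn from the same
stream and counted, with a warning if they exceed 0.1% of M (their
probability is negligible at realistic n, and redrawing just conditions the
null on testability).  The simulation is vectorised: a block of outcome
vectors becomes cumulative sums over tie groups, and all B-statistics in
the block are integrated exactly against the fixed mROC in array
operations (one stable argsort merges each replicate's breakpoints with the
mROC's; the running count of replicate-origin breakpoints identifies the
linear piece of each curve covering every union segment).

**Component p-values.**  `p = (1 + #{null ≥ observed}) / (M + 1)`, one per
statistic.  This deviates from the plain `1 − eCDF` estimator: the add-one
form is strictly positive, exactly uniform on the `1/(M+1)` grid under the
null, and breaks observed-vs-null ties conservatively.

**Combination.**  `Un = −2(log pA + log pB)` would be chi-square with 4 df
if the components were independent; they are not (same data).  The paired
null replicates carry the dependence: each replicate is scored against the
whole null sample (self-inclusive eCDF, cost O(M log M), bias O(1/M)) to
give null pairs `(pA*, pB*)` and null draws `U*`.  The mean and variance of
`U*` are matched to a scaled chi-square (`scale = V/2E`, `df = 2E²/V`), and
the unified p-value is the upper-tail probability of `Un/scale`.  With
independence imposed on continuous statistics the match recovers Fisher's
rule (df → 4, scale → 1, verified in the tests); note that heavily
discrete statistics (e.g. `An` at small n, which lives on a 1/n grid)
legitimately pull the matched df below 4 even under independence, because
the null p-values themselves are then super-uniform.

All randomness descends from a single user seed through
`numpy.random.SeedSequence` spawning, with a fixed block layout, so results
are bit-reproducible and order-independent.

## Comparator tests

* **Hosmer-Lemeshow**, decile groups by linear-interpolation quantiles of
  predicted risk, ties to the lower bin, statistic
  `Σ (O−E)² / (E(1−E/m))`.  Zero-variance bins (all risks exactly 0 or 1)
  are merged with a neighbour and recorded; fewer than 3 usable bins is an
  error.  *Degrees of freedom*: the default is one df per (post-merge) bin.
  The classical `G − 2` correction accounts for parameters estimated from
  the same data; in external validation nothing is estimated from the
  sample, each bin contributes an approximately independent squared
  standardised binomial, and using `G − 2` anyway makes the test markedly
  anticonservative (9.4% rejection at nominal 5% in the package's own
  true-null study at n = 250, versus 3.4% with df = G).  The
  development-data convention remains available via
  `df_convention="development"`.
* **Likelihood-ratio recalibration test** of weak calibration: fit
  `logit P(Y=1) = α + β·logit(pi*)` by IRLS (statsmodels GLM/Binomial,
  deviance tolerance 1e-8, max 100 iterations) and refer twice the
  log-likelihood gap from `(0, 1)` to chi-square(2).  Non-convergence and
  complete separation raise named errors.  Risks are clipped to
  `[1e-12, 1 − 1e-12]` before any logit; curve algebra itself accepts
  exact 0/1 risks (the weights handle them).
* **t-test** of the differences `Y − pi*` against mean zero (two-tailed).

## Synthetic-data generator

The generator defines the study conditions; it is not tuned.  A single
predictor `X ~ Normal(0, 1)` with true risk `p = expit(X)` underlies the
two miscalibration families:

* linear: `logit(pi*) = a + b·X`, `a ∈ {0, 1/4, 1/2}`, `b ∈ {1/3, 2/3, 1,
  4/3, 5/3}` — weak and moderate calibration coincide, so the LR test is
  the theoretical gold standard;
* nonlinear: `logit(pi*) = a + b·sign(X)·|X|^(1/b)` — odd in `X`, so the
  mean predicted risk depends on `a` only while the calibration curve bends
  (S-shape); the calibration slope barely moves, which is precisely where
  slope-based tests fail;

with `n ∈ {100, 250, 1000}` (the packaged `data/nonlinear_grid.yaml` holds
the full 45-scenario factorial).  The casemix family validates the fixed
model `pi* = expit(X)` in populations with predictor SD
`∈ {1, 0.5}` and association slope `∈ {1, 0.5}`.

What the generator does *not* emulate: multiple correlated predictors,
finite development samples (the "external model" is known analytically),
covariate shift beyond a variance change, non-logistic true risks, and
outcome dependence between subjects.  Passing tests therefore demonstrate
the statistical properties of the procedures under a clean
single-predictor logistic world, not robustness to real-data pathologies.

`population_auc` provides two independent oracles for every scenario's
population AUC: large-n simulation (n = 10^6, Monte-Carlo SE ≈ 0.0005) and
deterministic 1-D integration.  Predictions are monotone increasing in `X`
in every family, so the AUC reduces to `P(X_case > X_control) =
∫ f1(x) F0(x) dx` with `f1 ∝ φ_sd(x)·p(x)`, `f0 ∝ φ_sd(x)(1 − p(x))`;
this is evaluated by trapezoid on 240,001 nodes spanning ±12 predictor SDs
(error ~1e-9, far below the quantities compared).  The mean-predicted-risk
oracle uses adaptive quadrature (scipy `quad`) split at 0, where the
`sign(X)` kink sits.

A note on the stylized case-mix panels: the population AUCs of the four
panels are 0.7395, 0.6344, 0.6344 and 0.5696 (both oracles agree).
Published figures quoting 0.740 / 0.641 / 0.641 / 0.584 for this
construction are consistent with single simulated samples of roughly 10^4
observations (AUC sampling SE ≈ 0.0055), and the acceptance checks compare
at that precision rather than pretending the printed digits are population
values.

## Power studies and scales

`run_power_study` crosses scenarios with the five tests (mean calibration,
ROC equality, unified, Hosmer-Lemeshow, likelihood ratio), rejecting at
`p ≤ α`.  Every (scenario, replicate) pair derives its own data and
null-simulation streams from the master seed, so tables are reproducible
and order-independent.  Reported Monte-Carlo SE is `sqrt(p̂(1−p̂)/R)`; the
worst-case SE-0.01 design needs R = 2,500 replicates.

Desk scales used by the shipped studies (chosen once, as the package's own
defaults): population AUCs at n = 10^6; type-I error at 500 replicates,
n = 250, M = 2,000; LR power at 500 replicates, n = 1000; unified/HL power
at 100 replicates, M = 2,000; p-value uniformity via Kolmogorov-Smirnov on
~300-400 calibrated replicates at n = 100, M = 500.  At these scales the
binomial bands quoted in the tests are decisive for every claim checked.

## Numerical choices and edge cases

* Curve vertices are exact rationals of counts divided by class totals;
  the final vertex is pinned to (1, 1) to absorb last-bit cumsum drift.
* Ties between an observed statistic and null draws count toward the
  p-value (conservative).
* `mroc` requires `0 < Σ pi < n`; all-zero or all-one risk vectors have an
  empty implied class.  `model_based_cstat` additionally requires two
  distinct risk values (no informative pairs otherwise), although the
  all-tied *curve* is well-defined (the chance line).
* Single-class observed outcomes raise a dedicated error explaining that
  the calibration null is not testable.
* `unified_pvalue` raises with diagnostics if the null `U*` sample has
  non-positive mean or variance (pathological nulls).

## Known limitations

* No asymptotic (simulation-free) null approximation for `Bn`.
* No confidence bands, smoothed/binormal ROC models, or partial AUC.
* No multiplicity control across subgroup analyses; callers own that.
* Binary outcomes only; categorical and time-to-event extensions are out
  of scope.
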