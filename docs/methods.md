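# Methods

This note records the statistical model, the simulation design the package
emulates, and the numerical and design choices made where the procedure
left room for judgement.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Measurement model

All modules share one dichotomous item response model, the two-parameter
logistic (2PL)

P(Y_ij = 1 | θ_i, α_j, β_j) = σ( D · α_j · (θ_i − β_j) ),  σ(z) = 1/(1+e^−z),

with person trait θ_i (logits), item discrimination α_j > 0, item
difficulty β_j (logits), and the scaling constant **D = 1.702** fixed in
every evaluation — data generation, calibration, CAT scoring and both MCMC
steps — so all difficulties live on a single normal-ogive-consistent
metric.  The 1PL model is the special case of a common discrimination.

## Synthetic data: what the generator emulates

The generator reproduces the design of a mode-effect validation study for
a patient-reported-outcome item bank:

* **Item bank** — 100 items; β drawn uniformly (with replacement) from the
  25-point grid −3.0, −2.75, …, +3.0 logits.  1PL: α ≡ 1.  2PL:
  α ~ lognormal(log-mean 0, log-SD 0.5) redrawn until inside [0.5, 2.5].
  Rejection, not clipping: clipping would pile probability mass exactly on
  the bounds, which nothing in the design implies.  Note the asymmetry
  with the *prior* used in the DIF analysis (below), which is
  variance-parameterized.
* **P&P validation sample** — 500 simulees, θ ~ N(0, 1), complete
  responses.
* **CAT sample** — 3000 simulees, θ ~ N(μ_CAT, 1) with μ_CAT ∈ {0, 1};
  complete 100-item response matrices are generated first and the adaptive
  test then reveals 30 of the 100 cells per person.
* **Mode DIF** — uniform (difficulty-only) DIF on 10% or 30% of items,
  magnitude 0.42 or 0.63 logits (the conventional ETS "B" and "C"
  classes), sign ± by a fair coin per item.  CAT-mode responses for item j
  are generated from the *estimated* P&P difficulty β̂_j plus the item's
  shift, with the *true* discrimination — mimicking an operational CAT
  whose item parameters came from the paper calibration while respondent
  behaviour has drifted.

What the generator does **not** emulate: non-uniform (discrimination) DIF,
polytomous responses, local dependence, multidimensionality, non-normal
trait distributions, item-exposure control and variable-length stopping.
Passing tests therefore demonstrate the operating characteristics of the
detectors under a clean, correctly specified uniform-DIF regime, not their
robustness to those violations.

## Calibration (marginal ML, Bock–Aitkin EM)

Item parameters are estimated by maximizing the marginal likelihood with
the latent trait integrated against a fixed N(0, 1) density (the model is
identified by fixing the θ SD at 1).  Choices:

* Gauss–Hermite quadrature, 41 probabilists' nodes (weights renormalized).
* E-step via log-sum-exp; M-step is a weighted logistic regression of the
  expected endorsement counts on the node locations in the slope/intercept
  parameterization z = a·x + c (a = Dα, c = −aβ), which is concave; it is
  solved by damped Newton (step-halving), per item for the 2PL and jointly
  for the common slope + per-item intercepts (arrow-structured Hessian)
  for the 1PL.
* Convergence: max |Δα|, |Δβ| < 1e-4 between cycles, cap 500 cycles.  The
  EM ascent property (marginal log-likelihood non-decreasing) is asserted
  in the tests to 1e-8.
* Items endorsed by everyone or no one carry no information about a finite
  difficulty; they are excluded with a warning (estimates NaN).  The study
  harness pins such items at ∓4 logits so the CAT never selects them.
* **Bounded slopes.** Near-degenerate items (e.g. 498 of 500 endorsements)
  have a weakly identified, sometimes divergent ML slope.  Estimated
  discriminations are bounded at `alpha_max = 3.0` by default — generously
  above the range health-outcome banks field (rarely past 2.5) — the same
  kind of stabilization BILOG-class calibrators apply through slope priors
  or bounds.  Deliberately *not* a Bayesian prior, to keep calibration
  free of the priors used later in the DIF analysis.
* Standard errors come from per-person score cross-products
  (block-diagonal by item, delta method to the α/β scale) and are
  descriptive only.
* Correctness was established against an independent direct maximization
  of the same marginal likelihood (L-BFGS-B) on small simulated data.

## CAT engine

Fixed-length test (default 30 items), first item selected at θ = 0,
selection by maximum Fisher information D²α²P(1−P) at the current
estimate with deterministic lowest-index tie-breaking, responses replayed
from the pre-generated complete matrix, ability re-estimated by maximum
likelihood after every item.  The trait log-likelihood is concave, so the
MLE is found by bisection on its monotone derivative (54 iterations on
[−4, 4], ~5e-16 interval width); all-endorsed / none-endorsed patterns
have no finite maximizer and are clamped to ±4.0, which covers the ±3
generating range with margin and keeps the test runnable from the first
item.  The standard error is 1/√(test information at θ̂).  Selection and
scoring always use the calibrated P&P parameters; the replayed responses
came from the (possibly DIF-shifted) generating parameters.

This is an idealized, fully deterministic max-information CAT.  Measured
on 1PL banks it attains a mean reported SE around 0.23–0.26 (depending on
the bank realization) and CAT-to-full-bank ability correlations near 0.99;
operational CAT engines with exposure control or randomized selection are
somewhat less efficient per item, so published figures from such software
can show slightly larger SEs and lower CAT–full correlations at the same
test length.

## Bayesian DIF analysis

Priors (the second argument is a **variance**): θ ~ N(0, 1),
α ~ Lognormal(0, 0.5) (i.e. log α ~ N(0, 0.5)), β ~ N(0, 2).  These are
semi-informative: tight enough to regularize items the CAT rarely
administers, loose enough that a 0.63-logit shift is recoverable.

Sampling is adaptive random-walk Metropolis within Gibbs over three
blocks — θ (per person), log α and β (per item).  Persons are independent
given items and items independent given persons, so element-wise
acceptance within a block is a valid update.  Proposal scales adapt toward
the 0.44 scalar-optimal acceptance rate during burn-in (multiplicative
update every 25 iterations, scales clipped to [1e-3, 10]) and are frozen
afterwards, so retained draws come from a fixed-kernel chain.  Default
schedule: 3 chains with dispersed prior-drawn starts, 1000 burn-in + 500
retained each (1500 retained draws per parameter).  Convergence is
monitored by the classic split-chain potential scale reduction factor
(computed directly; values above 1.2 are logged as warnings and the
analysis proceeds — per-item difficulties in sparsely administered cells
mix slowest).

Step 1 (pooled θ) runs this sampler on the stacked P&P + CAT data
(unobserved CAT cells contribute nothing to the likelihood, implemented by
evaluating only observed cells in gathered form) and carries each person's
**posterior mean** θ forward — the procedure treats the Step-1 ability as
a fixed point value; propagating posterior draws of θ is out of scope.
Step 2 fixes θ and samples item parameters independently per mode in one
joint loop (mathematically equivalent to two separate runs).  Mode-specific
discriminations are sampled in both the 1PL- and 2PL-generated conditions
(the priors include α and nothing constrains it across modes), but only
the difficulty draws enter the DIF statistics.  An item never administered
by CAT keeps its prior as the β^CAT posterior; items with fewer than
`min_usage` (default 50) CAT administrations are flagged `low_usage`.

Per item, on the draws d_j = β_j^CAT − β_j^P&P:

* **Robust Z** = Med(d) / (0.74 · IQR(d)), with the IQR as Q3 − Q1 under
  linearly interpolated (type-7) quantiles — stated explicitly because RZ
  is sensitive to the quantile rule; 0.74·IQR of a normal sample is within
  0.2% of its SD.  A zero IQR (degenerate posterior) yields a signed
  infinity with a warning.
* **95% CrI** = empirical 2.5/97.5 percentiles of d; ΔCrI is the smaller
  absolute bound when the interval excludes zero, else 0 (the sign is
  discarded; direction is recoverable from the bounds).
* Flags at the α = .05 cutoffs: |RZ| > 1.96 (strict) and ΔCrI ≠ 0.

Sampler correctness is checked in the tests against a dense 2-D numerical
integration of the exact single-item posterior (agreement of posterior
mean and SD within 2%).

## Study harness and evaluation

The fully crossed design — model (1PL/2PL) × DIF size (0.42/0.63) × DIF
percentage (10/30) × μ_CAT (0/1) — gives 16 conditions, default 10
replications each (configurable; reduced-scale sweeps use fewer
replications and smaller CAT samples, with correspondingly wider Monte
Carlo bands).  Each replication runs the full pipeline
(bank → P&P data → calibration → DIF injection → CAT data → CAT →
three-step analysis) from named child seeds of one master seed, so any
run is bit-reproducible.  TP% is the flag rate among DIF-true items, FP%
among DIF-false items; overall sensitivity/specificity/correct
classification pool all items × replications × conditions.

ROC analysis follows the two-stage recipe: because both statistics signal
DIF at either sign, a logistic model with linear + quadratic terms of the
statistic predicts DIF truth, and the AUC (Mann–Whitney form) is computed
on the fitted probabilities.  The RZ-vs-CrI AUC difference is tested with
a DeLong-type correlated-AUC contrast (midrank influence components, 1-df
chi-square); the exact chi-square procedure behind the published contrast
is unspecified, so this standard construction stands in.  The contrast is
exactly calibrated for raw scores and conservative for refitted
probabilities (`fit_quadratic=False` selects the former).  Kurtosis in the
descriptive summary is reported as *excess* kurtosis and labelled as such,
since the convention is otherwise ambiguous.

Out of scope, by design: multilevel random-intercept regressions of
flag outcomes on item covariates, and polynomial smoothing of rates over
difficulty — the per-item record table the harness emits contains
everything needed to run both in external tools.  Item purification and
empirically recalibrated cutoffs are likewise not implemented.

## Known limitations

* Power depends strongly on CAT item usage; at reduced simulation scales
  (fewer simulees) per-item usage shrinks proportionally and true-positive
  rates drop well below their full-scale values, while false-positive
  control is essentially scale-free.
* The Step-1 point-value treatment of θ ignores ability uncertainty;
  extreme easy items inherit its matching error, which inflates false
  positives when the modes differ in mean trait level.
* The robust-Z null distribution is only approximately standard normal
  (slightly light-tailed in practice); fixed ±1.96 cutoffs are therefore
  mildly conservative.
* MCMC schedules are short by modern standards (chosen to match the
  procedure's design); split-R̂ warnings on sparsely administered items
  are expected and logged rather than fatal.
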