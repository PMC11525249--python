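# Methods

## Model

`mnrm` implements a multidimensional nominal response model: the probability
of category k ∈ {0..K} on item i for person n is

    p(Y_ni = k | θ_n) ∝ exp( Σ_d α_id · s_idk · θ_nd + γ_ik ),

a divide-by-total (softmax) form.  The scoring weights s_idk are **fixed in
advance** and carry the substantive interpretation: each item has one trait
row with equally spaced weights 0..K, an extreme-response-style (ERS) row
marking the endpoint categories, and a faking row holding the item's
desirability trajectory — how socially desirable each response category is in
the assessment context at hand.  Only the slopes α_id, the intercepts γ_ik
(k ≥ 1), and the latent correlation matrix Σ are estimated.  All weight rows
live on a common 0–6 metric (affine rescaling; such transformations are
absorbed by the slopes and intercepts and leave the likelihood invariant —
a property the test suite asserts).

Identification: γ_i0 = 0 per item; latent means 0 and variances 1, so latent
scores are z-scores.  `apply_identification` maps any parameter set onto this
scale through three likelihood-preserving transforms (intercept shift, mean
absorption, variance rescaling with slope compensation).

With a single trait dimension and weights 0..K the model reduces to a
generalized partial credit model; the tests exploit this by checking category
probabilities against an independent GPCM formula.

## Synthetic-data generator

The generator emulates a factorial simulation of a Big Five questionnaire on
a seven-point scale: five substantive traits, each measured by 6 or 12 items;
500/1000/2000 respondents; ERS present or absent; and faking impact
none/low/high — crossed with five **compositions of desirability
trajectories** per trait scale, from all-monotonically-increasing
(composition 1, maximal collinearity between trait and faking weights) to an
even mixture of all five trajectory types (composition 5).  The full product
is 180 conditions with 100 replications each by default.

Per replication: trait slopes ~ U(0.25, 0.75); ERS slopes ~ N(0.25, 0.1)
(untruncated) or 0; faking slopes 0, U(0, 0.5), or U(0.25, 0.75) by impact
level; category thresholds ~ N((−1.5, −0.9, −0.3, 0.3, 0.9, 1.5), 0.7·I),
converted to intercepts by negative cumulative sum (so the expected item
response distribution covers all seven categories); persons ~ MVN(0, Σ) with
meta-analytic Big Five intercorrelations randomly permuted over the ten trait
pairs (redrawn if the permuted matrix is not positive definite), ERS
orthogonal, and faking–trait correlations (.00, .10, −.10, .30, −.30).
Trajectory counts for non-integer proportions use fixed symmetric tables
(e.g., composition 4 at 6 items: 2/1/1/2; composition 5 at 6 items:
2/1/1/1/1 alternating with its mirror across traits).  Seeding is
hierarchical (master seed → condition → replication), so each replication is
bit-reproducible in isolation.

When models are *fitted* to simulated data, the faking weight rows are
contaminated with i.i.d. U(−0.5, 0.5) noise (clipped to [0, 6]) to emulate
that desirability weights in practice come from pilot ratings, not from the
generating truth.  The noise law is uniform by choice — bounded, symmetric,
shape-preserving on average — and its scale is configurable.

What the generator does **not** emulate: careless or inattentive responding,
acquiescence or midpoint response styles, missing data, person-specific
desirability perceptions, or item-content effects.  Passing tests therefore
show that the estimators recover the model's own data-generating process
under realistic parameter ranges, not that the model is correctly specified
for any particular real questionnaire.

## Estimation

**MH-RM (default).**  Marginal ML for the 6–7-dimensional models is obtained
by a Metropolis–Hastings Robbins–Monro scheme.  Each cycle: (1) a few
random-walk MH steps update each person's latent vector (proposal scale
adapted toward ~30% acceptance during burn-in); (2) each item takes one
damped Newton step on its complete-data multinomial-logistic log-likelihood
(concave given θ), scaled by the gain; (3) the latent covariance takes a
gain-weighted moment update from the imputed scores, followed by the exact
rescale-to-correlation transform with slope compensation.  Burn-in cycles use
a constant gain of 0.5; afterwards the Robbins–Monro gain 1/j applies and the
fit stops when the largest applied parameter change stays below `tol` (1e-3)
for `window` (3) consecutive cycles.  Non-convergence within the cycle budget
yields a flagged result, not an exception.

*Staged identification of the faking dimension.*  When trait and faking
scoring weights are strongly collinear (composition 1), the marginal
likelihood is nearly flat along a ridge trading trait correlations against a
general faking factor, and a naive stochastic fit can drift onto a spurious
bifactor-like representation.  The cure implemented here: during the first
two-thirds of burn-in the faking row of Σ is pinned to zero, so the prior
cannot lend trait variance to the faking scores and the faking slopes can
only grow on response structure the traits do not explain; the correlations
are then released.  Bias-dimension slopes also start small (0.1 vs 0.5 for
traits).  This reproduces both regimes correctly: when faking is absent the
faking model matches the plain model (no harm), and when faking drives the
data the faking slopes claim it.  The quadrature EM oracle on a
low-dimensional analogue confirms that the ML solution itself is consistent
(the spurious structure vanishes as n grows), so the staging is a basin-
selection device, not a change of estimand.

**Quadrature EM (oracle, D ≤ 4).**  A Gauss–Hermite EM in standardized
z-space (θ = Lz): the E-step computes posterior node weights, the M-step
takes ascent-guarded Newton steps per item (concave, step-halving) and
updates the latent correlations by numerical maximization over
hyperspherical Cholesky angles with a keep-old fallback — a generalized EM
whose quadrature log-likelihood is provably non-decreasing (asserted to 1e-8
in the tests).  Node counts: 21 per dimension for D ≤ 2, 15 for D = 3,
9 for D = 4.

**Marginal log-likelihood reporting.**  Exact GH quadrature for D ≤ 4; for
higher D a seeded antithetic Monte-Carlo estimate over prior draws (default
1000).  The MC estimate is adequate for AIC/BIC bookkeeping but too noisy to
discriminate nearby optima in high dimension; nothing in the package uses it
for that purpose.

**MAP scoring.**  Per-person posterior modes under MVN(0, Σ̂): the posterior
is strictly log-concave, so a vectorized damped Newton iteration finds the
unique mode; a grid-search oracle in the tests confirms it.

**Free-parameter bookkeeping.**  Slopes (one per loaded dimension per item),
K intercepts per item, and all D(D−1)/2 correlations.  For 30 items this
gives 220 / 255 / 291 parameters for the traits-only / +ERS / +faking
variants — hence 35 and 36 degrees of freedom for the nested likelihood-ratio
tests in `compare_models` (AIC = −2ℓ + 2p, BIC = −2ℓ + p·log N).

**Anchored item selection.**  `anchored_item_selection` refits with supplied
anchor slopes frozen, then ranks candidate items per trait by estimated trait
slope, optionally under required trajectory-type counts; ties break on item
id, and shortfalls raise an error naming the missing trajectory types.

## Evaluation statistics

- **Person recovery**: Pearson correlations between estimated (MAP) and true
  trait scores, Fisher-z transformed per trait; aggregates are
  back-transformed means.  Perfect correlations are capped at 1 − 1e-12
  before atanh so aggregation stays finite.
- **Latent-correlation recovery**: bias = mean deviation ρ̂_j − ρ_j over the
  ten trait pairs; RMSE = root mean squared deviation, both per replication.
- **Generalized η²**: balanced-design sum-of-squares decomposition
  (inclusion–exclusion over factor subsets) for the mixed design with the
  five simulation factors between replications and the fitted model as a
  repeated-measures factor; the denominator adds the subject
  (replication-within-cell) and within-residual strata to the effect, per the
  definition for designs where all factors are manipulated.  Values below
  .05 are treated as negligible in the tests.
- **Dependent correlations**: Steiger's Z for two correlations sharing one
  variable (the low-stakes score), one-tailed; validated against the
  closed-form symmetric case and a Monte-Carlo null calibration.
- **Mean shift by trajectory**: mean high-stakes minus low-stakes item score
  per desirability trajectory type, in rating-scale points.

## Desirability-trajectory classification

Items are classified from pilot desirability-rating histograms by minimal
Pearson X² across the five prototypes, with expected frequencies
proportional to the prototype weights (summing to the number of raters).
Negatively keyed items are recoded (category reversal) first.  Zero-weight
cells use a continuity rule: an empty expected cell with an empty observed
cell contributes nothing (so an exact-prototype histogram attains X² = 0),
while observed ratings in a zero-weight cell are scored against a floor of
0.5 — deliberately scale-invariant, so such cells penalize a type
quadratically as evidence accumulates.  Consequently X² is exactly linear in
a count rescaling only when no ratings fall in zero-weight cells.  Ties in
the minimum break toward the earlier type in the canonical order
(increasing → decreasing).  Empirical faking weights are the rating relative
frequencies rescaled to 0–6; a perfectly uniform histogram is degenerate and
rejected.

## Problem sizes and study-scale settings

The full design (180 × 100 replications, two fits each) is orchestration-level
work (`run_study`, resumable); the bundled tests and the acceptance script
run scaled-down versions chosen to exercise every claim: 10–20 replications
per checked condition, n = 500–2000, 6 items per trait, MH-RM with 150
burn-in cycles and 3 MH draws per cycle (the package default of 5 draws
trades a little runtime for slightly smoother gradients; both settings
converge to the same solutions).  The no-harm check uses composition 3 at
n = 1000, the representative mixed-trajectory case; the high-impact
superiority check uses composition 1 at n = 500, the hardest (fully
collinear) case.

## Known limitations

- Standard errors of item parameters and correlations are not computed.
- Limited-information fit statistics (C2, RMSEA, CFI, TLI) and polyserial
  correlations are out of scope.
- The quadrature EM is an oracle, not a production fitter: it is capped at
  D ≤ 4 and its correlation step is a numerical GEM.
- Missing responses are skipped by the likelihood if present, but the
  generator never produces them and no imputation is offered.
- The Monte-Carlo marginal log-likelihood for D > 4 has simulation error of
  a few units; likelihood-ratio tests between such fits should use ample
  draw counts.
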