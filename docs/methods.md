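# Methods

## Model

`healthexpect` estimates healthy life expectancy for older adults from
interval-censored longitudinal panels using a multistate life table built on
an interpolated Markov chain.  The state space is {healthy = 1,
unhealthy = 2, dead = 3}; both transitions between the living states are
allowed and death is absorbing.  Between interviews — which in surveys like
the CLHLS are three or four years apart — the process is modelled as a
discrete-time Markov chain on a fine step *h* (default one month).  For
origin state *j* the per-step probabilities follow a multinomial logit,

    p^{jk}(x) = exp(η_jk) / (1 + Σ_{k'≠j} exp(η_jk')),
    η_jk = a_jk + b_jk·(x − 80) + c_jk′ z,

with *x* age in years, *z* the covariate vector (loneliness, always
time-varying; optional baseline controls coded 0/1), and p^{jj} the
complement.  The dead row is fixed at (0, 0, 1).  Age enters centered at 80:
this is an affine reparameterization of an uncentered slope that keeps the
intercept and slope directions comparably scaled for the optimizer; an
internal rescaling of the slope directions (×10) preconditions L-BFGS
further.  Logits are clipped at ±50 before exponentiation.

The probability of moving between two interviews Δ years apart is the
ordered product of `Δ/h` one-step matrices with age advancing by *h* per
step and covariates held at their value at the episode's starting interview
(last observation carried forward).  Elapsed times are rounded to the
nearest whole number of steps (minimum one), with a warning if the rounding
is material.

## Likelihood

The data unit is the *episode*: a pair of consecutive interviews of one
person, or a final interview followed by an observed death with an exact
death age.  An episode from state *j* at age *x* to observed living state
*k* after Δ years contributes log _Δp_x^{jk}, the corresponding entry of the
interval product — which automatically sums over all unobserved living-state
paths.  A death episode contributes the log-probability of remaining in the
living states for the first m−1 steps and entering death during the step
containing the death age; the unobserved living path is again marginalized
through the matrix products.  Episodes with likelihood underflowing to zero
give −∞ with a diagnostic.

Fitting maximizes the weighted pseudo-log-likelihood Σ_i w_i ℓ_i by
L-BFGS-B with an exact gradient, propagated forward through the step
products alongside the state-occupancy vectors (a derivative-free
Nelder-Mead polish runs if the gradient search stalls).  Start values are
intercepts −4 for the death logits, −2 for morbidity/recovery, slopes zero.
Sampling weights are normalized to mean one across individuals before use.

The coefficient covariance is the inverse observed information (central
finite differences of the exact gradient) for unweighted fits.  When weights
vary across individuals the model-based covariance is inconsistent — its
middle matrix would need E[w²·ss′] rather than E[w·ss′] — so the default
becomes the sandwich estimator with per-individual score clustering,
A⁻¹BA⁻¹, where A is the observed information of the weighted objective and
B the outer-product sum of per-individual weighted scores.  `cov_type`
overrides the choice.

## Life-table quantities

**Stable (period) prevalence.**  w²(x) is the within-alive share of the
unhealthy state obtained by running the chain from age x − t to x and
renormalizing over the living states.  The window t grows in 5-year blocks
until both (i) the result is stable block-to-block and (ii) it is
independent of the starting state, to tolerance 1e−6; typical windows are
30–60 years, with a hard cap of 150 years.  The window extrapolates the
fitted logits below the sampled age range — mortality and morbidity logits
decline linearly going backward in age, so the early part of the window only
speeds mixing; this mirrors how period prevalence is obtained in classical
interpolated-Markov-chain software.

**Conditional expectancies.**  e^{ij}(x) = h/2·δ_ij + h·Σ_{u≥1} _u p_x^{ij},
the step sum of occupancy probabilities with a trapezoid end-correction.
The sum stops when surviving mass falls below 1e−8 or at the age cap
(default 110), where all living states are closed out to death so the sum is
finite by construction.

**Population-based LE/HLE.**  e^{·j}(x) = (1 − w²)e^{1j} + w²·e^{2j};
LE = e^{·1} + e^{·2} holds exactly because it is computed as that sum;
HLE/LE is reported in percent of the unrounded internals.

**Confidence intervals.**  Parametric bootstrap: coefficient vectors are
drawn from N(θ̂, Σ̂) (500 draws by default, seeded), each target is
recomputed per draw — vectorized over draws — and the 2.5/97.5 percentiles
reported.  A delta-method alternative is available for one-year transition
tables as a cross-check.

**Kannisto check.**  Simulated (or observed) old-age mortality is summarized
by the logistic hazard μ(x) = a·e^{b(x−x₀)}/(1 + a·e^{b(x−x₀)}), fitted by
binomial maximum likelihood to deaths/exposures by age band.  A positive *b*
with hazard bounded below one is the expected old-age pattern.

## Coding layer

Loneliness is the single-item "Do you often feel lonely and isolated?"
response: {always, often, sometimes} → lonely; {seldom, never} → non-lonely.
Physical health is the six Katz ADL items (eating, dressing, toileting,
indoor transfer, continence, bathing): any dependence → limitation.
Subjective health is 5-level SRH: {very good, good} → healthy.  Missing
responses propagate and the affected wave is dropped for that individual
while adjacent waves are kept — this maximizes usable episodes without
imputation.  Eligibility at baseline: community-dwelling, age 65–99, at
least one follow-up episode (an observed death counts), and a valid baseline
health measure; exclusions are logged per criterion in application order.

## Synthetic cohort generator

The generator is the package's ground truth: it simulates the same model
family the estimator fits.  Defaults emulate a CLHLS-like panel — 15,000
individuals, baseline ages 65–99 drawn from a Beta(1, 3.3) on that range
(mean ≈ 73), 52% women, ~25% lonely and ~96% ADL-independent at baseline,
~16% SRH-unhealthy, waves at 0/3/6/10 years with 7% per-wave dropout, and
two-point sampling weights (0.6/1.4) normalized to mean one.  The calibrated
truth anchors annual transition probabilities at age 80 for non-lonely men
(morbidity 0.06, death-from-healthy 0.05, recovery 0.25,
death-from-unhealthy 0.105) with log-slopes near the classical old-age
doubling rate (~0.09/y), a harmful loneliness effect (+0.30 on morbidity,
+0.35 on both death logits) and a protective female mortality effect
(−0.30).  These are qualitative calibrations, not fitting targets.

Loneliness evolves as its own two-state chain with per-step onset/remission
(stationary lonely share ≈ 25%).  An optional second morbidity process
generates SRH separately from ADL (sharing the mortality process), so
indicator-specific effects can be planted in opposite directions.  Raw
questionnaire columns (5-level loneliness labels with a configurable mixture,
six ADL flags, 5-level SRH labels) are emitted so the coding layer is
exercised end-to-end.  Death ages are exact (at step resolution);
observation adds dropout and reports a death at the first attempted contact
after it.  States are observed without error by default (an optional
misclassification rate defaults to zero).

What the generator does *not* emulate: item-level questionnaire structure,
informative attrition, interviewer or proxy-response effects, weight
calibration to census margins, and within-interval reporting error in death
dates.  Passing tests on synthetic data therefore demonstrate correctness of
the estimation machinery under the stated model, not robustness to these
real-data complications.

## Verification design

* Closed-form oracles: on age-constant chains, interval probabilities must
  equal matrix powers; conditional expectancies must match the fundamental
  matrix h(I−Q)⁻¹ − (h/2)I; stable prevalence must match the renormalized
  dominant left eigenvector of the living block.
* Exact-arithmetic checks: the reporting operations reproduce the derived
  statistics printed alongside the published LE/HLE tables wherever those
  are exact arithmetic on the printed entries (some published derived values
  reflect unrounded internals; the reporter therefore emits both
  "from-rounded" and "from-internal" columns).
* Parameter recovery: 20 cohorts of 10,000 simulated from a known truth
  (quarter-year step, waves 0/3/6/10) are refitted; each true coefficient
  must fall inside its 95% Wald interval in ≥ 90% of replicates.  For this
  experiment loneliness is held fixed at its baseline value so the
  generating process lies exactly in the fitted class — with within-interval
  loneliness switching the carried-forward covariate makes the likelihood an
  approximation and coverage of the "true" coefficient is not a meaningful
  check.  The experiment uses the generator's default two-point weights,
  which is what makes the sandwich covariance the right default.
* Qualitative pattern: the harmful planted loneliness effect must reproduce
  lonely LE < non-lonely LE and lonely HLE < non-lonely HLE at ages
  65/75/85 in every replicate.

## Numerical choices and problem sizes

Step *h* defaults to one month for analysis; the test-suite experiments use
a quarter-year step, which keeps the 20-replicate recovery study at roughly
four to five minutes while leaving discretization error well below sampling
error at these sample sizes.  Elapsed-time rounding is to the nearest step;
ties cannot occur for wave designs whose offsets are step multiples.
Reporting rounds to one decimal, half away from zero, and only at the
reporting layer.  Bootstrap draws and all simulation are seeded through
`numpy.random.default_rng`; identical (input, config, seed) reproduce
byte-identical pipeline outputs.

## Known limitations

* Two living states only; no frailty or random effects; no continuous-time
  intensity formulation.
* The covariate process is carried forward within episodes; when a
  time-varying covariate switches between interviews the likelihood is an
  approximation (shared with standard panel multistate practice).
* Exact death dates are assumed known by default (as when informants report
  dates); the unknown-date mode marginalizes the death time over the
  interval (the likelihood becomes the dead-column mass at the reporting
  contact), which discards the timing information and widens intervals.
* Wald/parametric-bootstrap inference relies on large-sample theory; with
  few episodes per origin state the covariance can be ill-conditioned (a
  pseudo-inverse fallback warns when the information matrix is singular).
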