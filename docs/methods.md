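# Methods

This note documents the statistical machinery of `jajcat`: the models, the
estimators, the synthetic world the simulations inhabit, and the numerical
and design choices made where more than one reasonable option existed.

## 1. Task and measurement model

A JaJ item of length *L* is an ordered sequence of *L* ball positions, each
i.i.d. uniform over the six marked screen positions (repeats allowed), paired
with i.i.d. same/different hand judgements.  Recall is scored all-or-nothing,
so the probability of passing an item by blind guessing is exactly 6⁻ᴸ
(≈ .167 at L = 1, < .03 from L = 2 on).

The measurement model is an explanatory (LLTM-style) item response model:

    logit P(y_ij = 1) = β₀ + β_l1·[L_i = 1] + β_len·L_i + u_j,  u_j ~ N(0, σ²).

Item difficulty is not a free parameter per item but a linear function of
length; the dummy gives length-1 items their own offset because both guessing
and (plausibly) the storage mechanism differ there.  No guessing asymptote is
modelled: with all-or-nothing scoring over six positions the 3-PL `c` would be
at most .167 on two of the fourteen static trials, and the dummy already
absorbs that anomaly.

Standardising ability (θ = u/σ) yields a one-parameter logistic model with
common discrimination a = σ and difficulty b(L) = −η(L)/σ, where η is the
fixed-effects predictor.  The package verifies algebraically (to machine
precision, in tests) that this transformation reproduces the mixed-model
probability.

**Default calibration.**  β₀ = 0.86, β_l1 = 1.44, β_len = −0.59 (SEs 0.21,
0.19, 0.04).  σ is not separately published; it is anchored through the one
published quantity linking the two scales — the length-2 difficulty of 0.13 —
giving σ = 0.32/0.13 ≈ 2.4615.  Difficulties for lengths 1–7 are then
−0.695, 0.130, 0.370, 0.609, 0.849, 1.089, 1.328.  Anything that consumes
item parameters (bank generation, estimation, simulation) flows through this
single mapping.

## 2. Calibration by marginal maximum likelihood

`ExplanatoryIrtModel.fit` maximises the marginal likelihood, integrating the
per-participant random intercept out of each participant's likelihood.  The
integral is handled by the Laplace approximation by default (`n_quadrature=1`)
or adaptive Gauss–Hermite quadrature centred and scaled at the per-participant
posterior mode (`n_quadrature` up to ~15).  Laplace is the default because it
is the default of the reference mixed-model implementations for this model
class and is, at this design (14 Bernoulli observations per cluster),
indistinguishable from AGQ-7 in replicate recovery runs.  The fit is verified
against `lme4::glmer` in the test suite and agrees to ~1e-5 on all four
parameters.

Implementation notes:

* inner problem: per-cluster Newton iterations on the conditional mode
  (vectorised over clusters via `bincount`);
* outer problem: Nelder–Mead warm start followed by BFGS on
  (β₀, β_l1, β_len, log σ);
* standard errors: central-difference Hessian of the negative marginal
  log-likelihood at the optimum, inverted;
* σ = 0 data: the boundary estimate has sampling spread of order 0.2 at this
  design — identical to lme4's behaviour — so "no random effect" should be
  read as σ̂ ≪ 1, not σ̂ = 0.

Predictive accuracy classifies each response as correct when the predicted
probability exceeds 0.5 — either marginal (fixed effects only; at the default
calibration only length-1 items are predicted correct) or conditional on the
estimated intercepts.  On data simulated at the calibration design the two
land at ≈ 71% and ≈ 87% respectively; the exact marginal expectation of the
fixed-effects classifier under the default model is 0.7135.

## 3. Ability estimation

Let S(θ) = Σ a(y_i − p_i) be the score function, I(θ) = Σ a²p_i(1−p_i) the
test information and J = dI/dθ.

* **Bayes modal (BM)**: root of S(θ) − (θ − μ)/τ² under the N(μ, τ²) prior
  (default N(0, 1)).  The posterior is strictly log-concave, so the root is
  unique; it is found by bracketed Brent root finding on [−6, 6].  The interim
  SEM defaults to 1/√(I + 1/τ²), i.e. it includes the prior precision; this is
  configurable (`SearchConfig.bm_sem_includes_prior`) because it affects
  SEM-threshold termination and the convention is not universal.
* **Warm weighted likelihood (WL)**: root of S(θ) + J/(2I), the maximiser of
  logL + ½·log I.  It is finite for all-correct and all-incorrect patterns
  (for n items at a common b, the implied success probability is
  (n+½)/(n+1), putting the estimate ≈ b + ln(2n+1)/a).  The weighted
  objective is *not* globally concave: for difficulty spreads ≳ 1 at a = 2.46
  it can be bimodal, with θ = 0 a local minimum for a symmetric pair.  The
  implementation therefore scans a coarse grid for every decreasing zero
  crossing and returns the candidate with the highest objective value.  WL
  SEM is 1/√I(θ̂).
* **Grid oracle**: an exhaustive arg-max over a dense θ grid of any of the
  three objectives, used as the independent referee in tests, never in
  production.

Search interval [−6, 6]: wide enough that every observed floor/ceiling of the
published design is an interior point, so reported extremes are properties of
the estimator, not clipping.

## 4. The adaptive engine

Start rule: a uniformly random length-2 item (b = 0.13, the average ability
of the calibration population at the task's centre).  Selection: Urry's
criterion — uniform draw among unadministered items whose |b − θ̂| is within
`selection_epsilon` (default 1e−9, i.e. exact ties only) of the minimum.
Because same-length items share one difficulty, the tie set is typically the
whole remaining pool of one length, which provides natural exposure control;
with equal discriminations the criterion coincides with maximum-information
selection (asserted in tests).  Termination: `max_items` (default 14), or an
optional interim-SEM threshold, whichever comes first.  Final score: WL over
all administered items.  No item repeats within a session.

Default bank: 20 items per length 1–7.  The deployed bank size is not
published; 20 per length is large enough that the random-among-closest rule
has real exposure control and that no 20-item session can exhaust a length.

## 5. The synthetic world

All evaluation inputs are simulated from the calibrated model; there is no
external data.  Simulees respond Bernoulli(p_correct(θ, item)) — hand
judgements are generated but assumed error-free, and response times,
practice/fatigue and motivation effects are not modelled.

* **Calibration analogue**: 244 participants × the static form, abilities
  N(0, 1) (the calibration population's defining property).
* **Static-form analogues**: examinee populations are normal with the
  published sample moments — N(0.63, 0.97) for the adult laboratory sample,
  N(0.94, 0.68) for the adolescent sample.
* **Adaptive analogue**: N(1.16, 0.54).
* **Score-range experiment**: a uniform grid of 200 true abilities over
  [−4, 4.15] with 10 replicate sessions per (ability, length) cell at each
  fixed test length 5..20.  Grid resolution and replicate count are not
  published; these values give stable extrema at desk scale because the
  extrema are produced by all-correct/all-incorrect sessions at the longest
  length, which occur with near-certainty at the grid edges.

The normal approximation matters: the real adolescent samples were skewed and
ceiling-compressed (kurtosis up to 3.8).  Consequences observed in this
package's replications: Cronbach's α of the static form computed from the
N(0.94, 0.68) world is ≈ 0.835, noticeably above the published .78 — a
mismatch of the *population shape*, not of the response model — while the
SEM/marginal-reliability replications (which are driven by the information
function rather than by score-distribution shape) land on the published
values.  A green simulation test therefore establishes consistency with the
model world, not with every feature of the empirical samples.

**Score range.**  Under WL final scoring the experiment reproduces the
published ceiling (≈ 2.79–2.84 vs 2.86) but yields a floor of ≈ −2.19 rather
than the published −1.89.  The floor of a WL-scored all-incorrect 20-item
session at the easiest difficulty is b_min − ln(41)/a ≈ −2.2; −1.89 is
instead very close to what a Bayes-modal *final* estimate with the N(0, 1)
prior would give (≈ −1.97), while BM would put the ceiling near 2.44, far
from 2.86.  No single final estimator reproduces both printed extremes under
the derived parameters; the package follows the documented scoring rule (WL)
and reports what it computes.

## 6. Other statistics

* **Empirical marginal reliability**: 1 − mean(SEM²)/var(θ̂) with sample
  variance (ddof = 1).  The model-based variant (integrating information over
  a population) is out of scope.  Negative values are returned with a warning
  rather than clipped.
* **Cronbach's α**: k/(k−1)·(1 − Σ item variances / total-score variance) on
  the persons × items 0/1 matrix.
* **Accuracy by length**: per-length means with binomial SEs and two OLS
  lines (all lengths; lengths 2–7 only), mirroring the task's descriptive
  analysis.  A numerical-integration oracle for the marginal per-length
  probabilities backs the tests.
* **θ → span conversion**: the default rule reads span as the continuous
  length at which p = 0.5: span(θ) = (β₀ + σθ)/(−β_len), using the L ≥ 2
  branch so θ = b(L) maps to exactly L; rounded values outside [0, 7] are
  flagged and excluded from means.  The rule is pluggable because the
  published mapping is not fully recoverable: it gives span(0) ≈ 1.46 where
  the published conversion reports 2.4 at θ = 0, so published span means are
  not reproduction targets.

## 7. Reproducibility and limitations

Every stochastic path takes an explicit seed (`numpy.random.Generator`);
banks, session logs and study summaries embed the seed that produced them.
Known limitations: only the one-random-intercept model family is supported
(by design); simulees are stationary (no learning/fatigue); the hand-judgement
stream is generated but not scored into the model; and the span conversion is
one defensible rule among several, documented as such.
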