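# Methods

## Model and procedure

`crmkit` implements the Bayesian continual reassessment method for
single-agent phase I trials with a binary DLT endpoint. The working model
is the one-parameter empiric (power) model

    R(d_k) = Pr(DLT at dose d_k) ≈ α_k^exp(a),    k = 1..K,

with skeleton constants `0 < α_1 < ... < α_K < 1` and prior
`a ~ N(0, σ_a²)`. The model is deliberately under-parameterized: it is not
expected to fit the whole dose-toxicity curve, only to approximate it well
near the target `θ`, which is what MTD estimation needs. Monotonicity of
toxicity in dose is assumed throughout; scenario validation rejects
non-monotone truth vectors.

Given per-dose DLT counts `y_k` out of `n_k` evaluable patients (replaced,
non-evaluable patients must be excluded by the caller), the log likelihood
is the binomial

    ℓ(a) = Σ_k [ y_k exp(a) log α_k + (n_k − y_k) log(1 − α_k^exp(a)) ].

The engine reports the posterior mean `â`, plug-in estimates
`p̂_k = α_k^exp(â)`, and recommends `argmin_k |p̂_k − θ|` with ties to the
lower dose. The plug-in-at-posterior-mean estimator (rather than the
posterior mean of each probability) is the convention of standard CRM
implementations and is what the worked conduct examples in the test suite
validate. Two conduct rules sit on top: escalation may not skip dose
levels (capped at one level above the most recent administered dose;
de-escalation is unrestricted), and the trial stops for safety when the
lower limit of the central 90% posterior interval for `R(d_1)` exceeds
`θ`. The first cohort is assigned to the design's starting dose without
consulting the model.

## Design calibration

**Skeleton.** The indifference-interval construction anchors `α_ν = θ` at
the prior-MTD dose ν and recurses outward: moving up,
`α_{k+1} = (θ+δ)^{1/s}` with `s = log(θ−δ)/log(α_k)`, i.e. at the
parameter value where dose k's model estimate equals `θ−δ`, dose k+1's
equals `θ+δ`; the downward recursion mirrors this. The construction
defines one doubly-infinite sequence anchored at θ, so changing ν merely
slides the K-window along it — skeletons with different ν agree exactly
where their indices overlap (this, not identity of downstream
recommendations, is the invariance the construction guarantees; with each
skeleton paired to its own calibrated prior, recommendations on the same
data can differ by the window shift). Defaults: `δ = 0.05` (inside the
ranges known to give robust operating characteristics for common targets)
and ν = ⌈K/2⌉, the median dose. Skeletons are kept at full precision
internally and rounded to 2 d.p. only for display.

**Least-informative prior.** Partition the `a`-axis into intervals
`A_1..A_K` where dose k is the model's MTD; boundaries solve
`α_k^exp(a) + α_{k+1}^exp(a) = 2θ` (bisection on [−20, 20], tolerance
1e−10; the left side is continuous and strictly decreasing). The prior MTD
distribution is `q_k(σ) = P(a ∈ A_k)` under `a ~ N(0, σ²)`; σ_a is chosen
on a grid (0.1–3.0, step 0.01, ties to the smaller value) to minimize
`max_k |q_k − 1/K|`. The worst-coordinate distance was chosen over
sum-of-squares because it directly expresses "no dose is prior-favoured";
for the default 5-dose, θ = 0.25 design it gives σ_a = 0.53 and
reproduces the conduct-mode estimates (0.21, 0.27) that pin this
calibration down to about ±0.03 in σ — a sum-of-squares objective gives
an indistinguishable value here. `K = 1` designs are degenerate (skeleton
= {θ}, no calibration) and are rejected by the calibrator.

## Numerical choices

* Posterior integrals: fixed 2001-point Simpson grid on `a ∈ [−10, 10]`,
  evaluated in log space with max-subtraction. Halving the grid changes
  `â` by < 1e−6 on realistic states; the test suite also checks `â` and
  the interval endpoints against an independent importance-sampling oracle
  (10⁶ prior draws, 3 standard errors).
* The 90% safety interval is equal-tailed: the 5th/95th posterior
  quantiles of `a` are found by inverting the trapezoid CDF on the grid
  and mapped through the decreasing function `a ↦ α_1^exp(a)` (so the
  a-quantiles swap roles). Equal-tailed was chosen over HPD as the
  conventional reading of a "90% probability interval"; for these
  unimodal, mildly skewed posteriors the difference is small.
* `α_k^exp(a)` saturates to 1 in floating point for very negative `a`;
  with observed non-DLTs the log likelihood floors to −∞ there rather
  than raising, which the quadrature handles naturally.
* Safety is checked at every update, before the next assignment; with no
  data the check runs against the prior alone and cannot trigger for any
  vague calibrated prior.

## Simulator

Each simulated trial draws patient outcomes as independent Bernoulli
variables at the assigned dose's true DLT probability, in dose-assignment
order, from a single seeded `numpy` Generator shared across all `nsim`
trials — results are bit-reproducible for fixed seed, nsim and design.
Termination, in order of precedence at each update: (1) safety stop (no
MTD declared); (2) the n-at-dose rule — evaluated at recommendation time,
counting all patients treated at the recommended dose regardless of
outcome — stops the trial and declares that dose the MTD; (3) at the
maximum sample size the MTD is the dose the engine would assign to the
next, unenrolled cohort (including the no-skip cap). With
`stop_count > max_n` (the default) every trial accrues to `max_n`.

Reported operating characteristics: per-dose selection %, per-dose mean
patients and mean DLTs, and % of trials stopped for safety; selection and
safety percentages sum to 100 before rounding. Tables round percentages
and means to 1 d.p.

The default study conditions used by the acceptance script and the
simulation tests are 1000 trials of 24 patients in cohorts of 2, starting
at dose 1, with the true curve set equal to the (rounded) default skeleton
so that dose 3 is the true MTD at exactly the target — a deliberately
hard scenario, since both neighbours of the MTD lie only 0.09–0.10 away
in toxicity. 1000 trials puts a Monte-Carlo standard error of about 1.6
percentage points on the selection percentages.

## What the simulator does and does not emulate

It emulates the sequential decision process exactly as conducted: cohort
accrual, model updates, escalation restrictions, stopping. It does not
model accrual times, patient replacement, late-onset or ordinal
toxicities, or covariates; outcomes are exchangeable Bernoulli draws.
Passing tests therefore demonstrate the decision logic and its
calibration, not robustness to the messiness of real accrual.

## Limitations

* One-parameter empiric model only; logistic or two-parameter working
  models are out of scope by design.
* Likelihood-only (non-Bayesian) CRM, two-stage designs with
  pre-specified escalation runs, and TITE weighting are not implemented.
* The least-informative calibration is a grid search; σ_a is resolved to
  0.01, which is finer than the design's sensitivity to it.
* Selection percentages under a given scenario carry Monte-Carlo error;
  raise `nsim` beyond the default 1000 to tighten protocol tables.
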