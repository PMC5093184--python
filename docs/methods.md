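# Methods

## The curve family

The package models the hazard of death for a subject with covariates `x`
and long-term exposure `z` as
`h(t|x,z) = h0(t)·exp{γ′x + β·ν(z)}` with
`ν(z) = f(z)·ω(z|μ,τ)`, `f ∈ {z, log z}` and
`ω(z|μ,τ) = {1 + exp(−(z−μ)/(τ·r))}⁻¹`. The logistic weight is a smooth
switch: below `μ` the exposure contributes little to the log hazard,
above `μ` it contributes `≈ f(z)`. Interpretation is easiest as a
variable risk coefficient `β(z) = β·ω(z)`.

Parameters and defaults:

- `μ` (μg/m³) — location of the switch. Chosen by the data via the
  percentile search; may be negative (a curve already saturated at the
  observed minimum).
- `τ` (unitless) — curvature relative to the exposure range `r`. The
  search uses {0.1, 0.2}: 0.1 gives a visible sigmoid without sharp
  curvature, 0.2 approaches power-of-concentration shapes; ≤0.001 is an
  indicator (used only for the explicit threshold special case).
- `r` (μg/m³) — fixed at max − min of the analytic sample and stored in
  the transform, so a fitted curve evaluates identically on any new
  population.
- `f_shift` — non-zero only for the threshold form `f(z) = z − T`.

The "large negative μ" used to saturate `ω` for the plain linear and
log-linear special cases is `min(z) − 10³·r`; with the logistic exponent
clipped at ±700 this drives `ω > 1 − 10⁻⁶` over any plausible range
without overflow. `f = log` takes the natural log of raw concentration
and rejects `z ≤ 0` rather than shifting: ambient PM2.5 is strictly
positive. Monotonicity of `ν` is guaranteed only where `f(z) ≥ 0`
(`z ≥ 1` for the log form); below that the curve may dip slightly and no
constraint is imposed.

Hazard-ratio curves are reported against a reference concentration; the
exported tables anchor at the grid minimum (curves start at the lowest
observed exposure). The derivative of the HR curve uses the analytic form
`β·ν′(z)·exp(β·Δν)` with `ν′ = f′ω + f·ω(1−ω)/(τr)`, verified against
central finite differences at 10⁻⁵ relative tolerance.

## Estimation

`β` (and the nuisance coefficients `γ`) maximise the stratified Cox
partial likelihood with `ν(z)` as a fixed covariate. The engine is an
exact Newton–Raphson on the partial log-likelihood with analytic gradient
and Hessian, vectorised over risk sets via per-stratum prefix sums; tied
event times use Efron's correction by default (Breslow available, mainly
because the brute-force oracles are simplest under it). Convergence:
relative log-likelihood change < 10⁻⁹, at most 100 iterations, with
step-halving; standard errors come from the inverse observed information.
Strata with zero events are dropped with a warning (they contribute
nothing to the likelihood); a transformed exposure that is constant
within every event-bearing stratum raises a degenerate-covariate error.
Left truncation and time-varying exposures are out of scope — the models
use fixed baseline exposure. The engine is cross-checked in the test
suite against lifelines' CoxPHFitter (coefficients, standard errors and
log-likelihood to ~10⁻⁵ relative) and against brute-force grid
maximisation on small fixtures.

## Model search

Step 1 fits the 16-model factorial grid (4 percentiles × 2 τ × 2 f) and
keeps the largest partial log-likelihood. Step 2 refits at the winning
μ-percentile ±5 points holding f and τ fixed — the walk is over μ only,
keeping the number of model runs small. Step 3 continues in the
improving direction until the log-likelihood stops increasing. The grid
extends below the observed minimum in multiples of the (P5 − min)
increment, labelled −5%, −10%, …, capped at 6 steps to bound runtime on
flat likelihood surfaces. Percentiles use linear interpolation between
order statistics (configurable; the convention is not otherwise pinned
down). Log-likelihood ties within 10⁻⁶ resolve toward the larger μ, the
flatter and more conservative low-end curve. The search is deterministic
given cohort and configuration, and never refits a (f, τ, μ) triple.

In practice the likelihood surface over (μ, τ) is flat along ridges of
similar curve shape — a larger τ with a smaller μ traces nearly the same
`ν(z)` as the generating (τ=0.1, μ at P50) curve — so the *selected*
label varies across replicates even when the fitted shape is right.
Selection summaries therefore report, besides the raw 5-point modal
percentile, a modal 10-point bin (edges at 10k±5, ties toward the median
selection), the granularity at which a location estimate is meaningful.

## Ensembles and uncertainty

All models fit during the search enter the ensemble with weights
`w_i = exp(LL_i − max LL) / Σ exp(LL_j − max LL)` (max-subtraction keeps
this stable at cohort-scale log-likelihoods ~ −3×10⁶). Every model has
the same parameter count, so likelihood and AIC weights coincide. A
report threshold (default 0.001) hides negligible models from summaries
but never from the mixture — truncating the sampled set would bias it.
Uncertainty draws pick model `i` with probability `w_i` and then
`β ~ N(β̂_i, se_i)`; hazard-ratio and derivative bands are pointwise
2.5/97.5 Monte-Carlo percentiles (default 10,000 draws; all draws flow
from one user-supplied seed).

## Impact assessment

`ΔD = M0·(1 − exp{−Δν(z^C, z^F)·β})·pop` per region, summed over a
scenario table; regions where concentration rose contribute negative
excess deaths. Uncertainty re-evaluates the scenario total per ensemble
draw and summarises mean, sd and empirical 95% interval. Because `Δν` is
non-linear in concentration, equal-sized changes at different points of
the exposure distribution produce different burdens; the linear special
case is the unique location-free member, and both behaviours are
asserted in the tests on constructed two-region scenarios.

## Pooling across studies

A study's excess-death distribution is reduced to a normal summary — from
retained draws, or from a printed mean and 95% CI via
`se = (upper − lower)/(2·1.96)`. Studies combine by DerSimonian–Laird
random effects: `τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))` with
fixed-effect weights `w_i = 1/se_i²`, pooled mean and se under
`w*_i = 1/(se_i² + τ²)`, and a normal-quantile 95% interval. DL with
normal quantiles reproduces the published combined burden rows from
their printed study-level inputs; REML is available behind a flag for
sensitivity. Pooling happens on the burden scale, not the curve scale:
the estimand is attributable deaths, and burden distributions remain
comparable even when the fitted curve shapes differ.

## Synthetic cohorts

The generator emulates the structure of a large mortality cohort at desk
scale:

- Exposure: `z = z_min + Gamma(k, θ)`, with `(k, θ)` solved so the median
  and the 99.5th percentile hit stated targets (defaults 12.4 and
  27.9 μg/m³ above a 1.4 floor, a PM2.5-like right-skewed law); the thin
  tail above the ceiling is clipped. With these targets the realised
  sample minimum sits near 3 μg/m³.
- Confounding: one standard-normal covariate shares a Gaussian copula
  with exposure (ρ = 0.3 by default); a second independent Bernoulli
  covariate exercises the γ-adjustment contract. Defaults
  γ = (0.3, −0.2).
- Survival: constant baseline hazard within each of 2 strata
  (multipliers 1.0/1.5), λ₀ = 0.005 per year, administrative censoring at
  20 years, event times by inverse transform on the exponential scale.
  Under the default curve (log form, μ at the median, β = 0.25 — about a
  1.9-fold hazard contrast across the range) this yields ~16% events at
  n = 20,000, a few thousand deaths.

What the generator does *not* emulate: exposure measurement/model error,
rich covariate batteries, time-varying baseline hazards, and informative
censoring. Passing recovery tests therefore demonstrate the estimator
and search behave correctly under the assumed data-generating law, not
robustness to the additional complications of real cohorts.

Recovery experiments fit the true transform per replicate (bias, 3-se
coverage of true β) and run the full search (selection histogram).
Problem sizes in the shipped tests and in `scripts/acceptance.py` are 20
replicates of n = 20,000 — small enough to run routinely, large enough
that coverage and the binned modal selection are stable across seeds.

## Numerical choices

- Logistic exponent clipped at ±700 (float64 overflow); ω saturates to
  exactly 1.0 beyond an exponent of ~37, which the open-interval claims
  acknowledge.
- JSON serialisation uses repr-precision floats: round-trips are exact.
- Newton–Raphson guards with step-halving and raises, rather than
  returning, on singular information or non-convergence.
- Seeds: every stochastic routine takes one integer seed
  (`numpy.random.default_rng`); replicate seeds are drawn below 2³¹ from
  the master seed.

## Known limitations

- The search holds f and τ at the Step-1 winner during the μ walk;
  whether the original procedure refits both τ at each new μ is
  ambiguous, and the economical reading was adopted.
- Monotone non-decreasing `ν` is not enforced for `z < 1` under the log
  form.
- The Cox engine supports right censoring and strata only — no
  counting-process entry/exit, no robust or clustered variances.
- Between-study pooling assumes the normal approximation of each
  excess-death distribution is adequate; heavy-tailed burden
  distributions would need quantile-based pooling.
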