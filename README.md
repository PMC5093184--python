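# crshape

Non-linear concentration-response survival models for air-pollution health
impact assessment.

Cohort studies of ambient fine particulate matter (PM2.5) and mortality
almost always assume the log hazard is linear in concentration, because a
linear covariate is what standard Cox software accepts. `crshape`
implements a flexible algebraic family of *non-linear* concentration-
response curves that still fit with ordinary survival machinery, plus the
downstream calculus that turns a fitted curve into attributable-death
estimates with honest uncertainty. It is aimed at environmental
epidemiologists and risk assessors who need curve shapes — thresholds,
supra-linear rises, sigmoids — identified from large cohorts and carried
through to burden estimates.

## The model

The hazard for a subject with risk factors `x` and long-term exposure
`z` (μg/m³) is

    h(t | x, z) = h0(t) · exp{ γ′x + β · ω(z | μ, τ) · f(z) }

where `f(z)` is `z` or `log z`, and

    ω(z | μ, τ) = 1 / (1 + exp(−(z − μ) / (τ·r)))

is a logistic weight with location `μ`, curvature `τ`, and exposure range
`r = max(z) − min(z)`. The product `ν(z) = f(z)·ω(z)` is a single fixed
covariate, so `β` is estimable with any Cox fitter; `β(z) = β·ω(z)` acts
as a risk coefficient that varies with concentration. Special cases:
`μ → −∞` recovers the linear and log-linear models, `f(z) = z − T` with
`ω(·| μ=T, τ=0.001)` a threshold at `T`, and `τ = 0.2` approximates
powers of concentration.

On top of the family the package provides:

- **Model search** — a three-step percentile-grid procedure: 16 Cox fits
  (μ at the 0/25/50/75th exposure percentiles × τ ∈ {0.1, 0.2} ×
  f ∈ {z, log z}), then a local walk of μ in 5-percentile steps
  (extending below the minimum by multiples of the P5 − min increment)
  until the partial log-likelihood stops improving.
- **Ensembles** — likelihood weights `w_i ∝ exp(LL_i − max LL)` over every
  model fit, with Monte-Carlo draws of (model, β) propagating joint
  model-choice and sampling uncertainty into hazard-ratio bands.
- **Impact assessment** — excess deaths for a region with baseline
  mortality rate `M0` and population `pop` moving from concentration
  `z^C` to `z^F`:  `ΔD = M0·(1 − exp{−Δν(z^C, z^F)·β})·pop`, summed over
  regions, with Monte-Carlo uncertainty from the ensemble.
- **Pooling** — DerSimonian–Laird random-effects combination of
  excess-death distributions across studies (normal approximation per
  study), so different cohorts' curves are merged on the burden scale
  rather than the curve scale.
- **Synthetic cohorts** — a seeded generator with a right-skewed
  (shifted-gamma) exposure law, a copula-confounded covariate, stratified
  constant baseline hazards, administrative censoring, and a known true
  curve, so the whole pipeline is testable end to end.

## Worked example

```python
from crshape import (SimulationDesign, default_true_curve, generate_cohort,
                     search, ModelEnsemble, ScenarioTable, scenario_uncertainty)

cohort = generate_cohort(SimulationDesign(true_curve=default_true_curve(), seed=11))
result = search(cohort)                     # 18 Cox fits on this cohort
ens = ModelEnsemble.from_search(result)
scenario = ScenarioTable.from_records([
    ("metro", 3.0e6, 0.009, 12.0, 9.0),
    ("city",  1.0e6, 0.010,  9.5, 7.5),
    ("rural", 4.0e5, 0.011,  6.0, 6.5),
])
est = scenario_uncertainty(scenario, ens, n_draws=10_000, seed=42)
```

Running `python examples/02_fit_and_search.py` prints, for that seed:

```
cohort: n=20000, events=3148, exposure 3.0-27.9 ug/m3
18 models fit; best: f=log, tau=0.2, mu=3.04 (0th percentile), beta=0.4670 (se 0.0377)
refit of the true transform: beta=0.2511 (se 0.0205; truth 0.25)
```

The true coefficient is recovered within one standard error, and the
likelihood weight spreads over several (μ, τ) pairs that trace nearly the
same curve — that spread is the model-choice uncertainty the ensemble
carries forward. `examples/03_impact_assessment.py` then shows a
two-model ensemble attributing `1049 (95% CI 831–1262)` avoided deaths to
the scenario above (2.53% of baseline deaths, the rural region negative
because its concentration rose), and that a 2 μg/m³ reduction yields
13.3 deaths at the low end of the exposure range but only 3.6 at the high
end under the sigmoidal curve — while the linear curve gives 14.1 in both
places. `examples/04_pooling.py` pools two national-scale study rows into
`61,933 (34,847–89,019)` excess deaths.

A thin CLI mirrors the workflow
(`crshape simulate | search | ensemble | hia | pool | export-curve`); run
`crshape --help`.

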