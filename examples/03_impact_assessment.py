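"""Excess deaths from a concentration-reduction scenario, with uncertainty.

Builds a small two-study-style ensemble, applies it to a region table
(population, baseline mortality, current and future PM2.5), and shows the
family's key risk-assessment property: where a change occurs in the
exposure distribution matters for a non-linear curve.
"""

import numpy as np

from crshape import (
    ExposureTransform,
    FittedRiskModel,
    ModelEnsemble,
    RiskCurve,
    ScenarioTable,
    make_special,
    scenario_excess_deaths,
    scenario_uncertainty,
)


def fitted(mu, beta, se, loglik):
    return FittedRiskModel(
        transform=ExposureTransform("log", mu=mu, tau=0.1, range_r=26.5),
        beta_hat=beta, se_beta=se, gamma_hat=(), loglik=loglik, n_events=0,
    )


# a sigmoidal-log optimal model plus a lower-mu competitor, as a search
# over a large cohort typically returns
ens = ModelEnsemble.from_models([
    fitted(mu=8.19, beta=0.0433, se=0.00446, loglik=-100.0),
    fitted(mu=1.38, beta=0.0802, se=0.00843, loglik=-101.75),
])
print("ensemble weights:", np.round(ens.weights, 3))

scenario = ScenarioTable.from_records([
    ("metro",  3.0e6, 0.009, 12.0, 9.0),
    ("city",   1.0e6, 0.010,  9.5, 7.5),
    ("rural",  4.0e5, 0.011,  6.0, 6.5),   # concentration rose here
])

est = scenario_uncertainty(scenario, ens, n_draws=10_000, seed=42)
print(f"\nexcess deaths avoided: {est.mean:.0f} "
      f"(95% CI {est.ci95[0]:.0f} to {est.ci95[1]:.0f}), "
      f"{est.percent_of_baseline:.2f}% of baseline deaths")
print("per region:")
for rid, v in est.per_region.items():
    print(f"  {rid:6s} {v:8.1f}")

# location dependence: same 2 ug/m3 reduction, low vs high end of the range
low = ScenarioTable.from_records([("low", 1e5, 0.01, 6.0, 4.0)])
high = ScenarioTable.from_records([("high", 1e5, 0.01, 26.0, 24.0)])
lin = RiskCurve(make_special("linear", 1.4, 27.9), 0.0071)
nonlin = ens.models[0].curve
print("\nsame-size change, different location (excess deaths):")
print(f"  linear curve:     low-end {scenario_excess_deaths(low, lin)[0]:6.1f}   "
      f"high-end {scenario_excess_deaths(high, lin)[0]:6.1f}")
print(f"  sigmoidal curve:  low-end {scenario_excess_deaths(low, nonlin)[0]:6.1f}   "
      f"high-end {scenario_excess_deaths(high, nonlin)[0]:6.1f}")
print(
    "\nThe linear curve attributes the same burden wherever the change\n"
    "occurs; the non-linear curve concentrates burden where its slope is\n"
    "steep, so identical reductions can differ several-fold in impact."
)
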