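"""Health impact assessment: excess deaths from concentration changes.

For a region with baseline mortality rate M0 and population pop, moving
from current concentration zC to counterfactual/future zF changes deaths
by

    dD = M0 * (1 - exp(-dnu(zC, zF) * beta)) * pop,

where dnu is the change in transformed exposure under the fitted curve.
Region totals add; uncertainty is propagated by evaluating the total over
Monte-Carlo draws from a model ensemble.  Because dnu is non-linear in
concentration, where a change occurs within the exposure distribution
matters, not just its size — the linear special case (dnu = zC - zF) is
the only location-free member of the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import ModelEnsemble, sample_curves
from .transforms import RiskCurve, delta_nu

__all__ = [
    "ScenarioTable",
    "ExcessDeathEstimate",
    "excess_deaths_point",
    "scenario_excess_deaths",
    "scenario_uncertainty",
    "population_weighted_mean",
]

SCENARIO_COLUMNS = ("region_id", "pop", "M0", "z_current", "z_future")


@dataclass
class ScenarioTable:
    """Region-level inputs for impact assessment.

    One row per region: population at risk, baseline mortality rate M0
    (deaths per person over the assessment period) and the current and
    future/past concentrations in ug/m3.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCENARIO_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"scenario table is missing columns: {missing}")
        if self.df[list(SCENARIO_COLUMNS)].isna().any().any():
            raise ValueError("scenario table contains missing values")
        if (self.df["pop"] < 0).any():
            raise ValueError("populations must be non-negative")
        if ((self.df["M0"] < 0) | (self.df["M0"] > 1)).any():
            raise ValueError("M0 must lie in [0, 1]")

    @classmethod
    def from_records(cls, records) -> "ScenarioTable":
        return cls(pd.DataFrame.from_records(records, columns=SCENARIO_COLUMNS))

    @property
    def baseline_deaths(self) -> float:
        return float((self.df["M0"] * self.df["pop"]).sum())


@dataclass
class ExcessDeathEstimate:
    """Monte-Carlo summary of the attributable-deaths distribution."""

    mean: float
    sd: float
    ci95: tuple[float, float]
    per_region: pd.Series
    percent_of_baseline: float
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.mean <= hi):
            raise ValueError("mean must lie within its interval")


def excess_deaths_point(M0: float, pop: float, dnu: float, beta: float) -> float:
    """dD = M0 * (1 - exp(-dnu * beta)) * pop for a single region.

    Positive when the transformed change times beta is positive (a
    reduction in exposure under a harmful curve), bounded above by the
    baseline deaths M0 * pop.
    """
    args = np.asarray(M0, float), np.asarray(pop, float), np.asarray(dnu, float), np.asarray(beta, float)
    if not all(np.all(np.isfinite(a)) for a in args):
        raise ValueError("inputs must be finite")
    return float(M0 * (1.0 - np.exp(-dnu * beta)) * pop)


def _region_deltas(s: ScenarioTable, transform) -> np.ndarray:
    return delta_nu(
        s.df["z_current"].to_numpy(float), s.df["z_future"].to_numpy(float), transform
    )


def scenario_excess_deaths(s: ScenarioTable, c: RiskCurve) -> tuple[float, pd.Series]:
    """Plug-in excess deaths: total and per-region breakdown.

    Regions where concentration increased (zF > zC) contribute negative
    deaths.  Domain errors (e.g. non-positive z under a log transform)
    are reported with the offending region ids.
    """
    try:
        dnu = _region_deltas(s, c.transform)
    except ValueError as exc:
        zc = s.df["z_current"].to_numpy(float)
        zf = s.df["z_future"].to_numpy(float)
        bad = s.df["region_id"][(zc <= 0) | (zf <= 0)].tolist()
        raise ValueError(f"concentration outside curve domain in regions {bad}") from exc
    per = (
        s.df["M0"].to_numpy(float)
        * (1.0 - np.exp(-dnu * c.beta))
        * s.df["pop"].to_numpy(float)
    )
    series = pd.Series(per, index=s.df["region_id"].to_numpy(), name="excess_deaths")
    return float(per.sum()), series


def scenario_uncertainty(
    s: ScenarioTable,
    e: ModelEnsemble,
    n_draws: int = 10_000,
    seed: int = 0,
    keep_draws: bool = True,
) -> ExcessDeathEstimate:
    """Excess-death uncertainty distribution under a model ensemble.

    Each draw picks a model by its likelihood weight and a beta from that
    model's normal law, then evaluates the scenario total; the summary is
    the empirical mean, sd and 2.5/97.5 percentiles.  Per-region values
    are the draw-wise means.
    """
    draws = sample_curves(e, n_draws, seed)
    pops = s.df["pop"].to_numpy(float)
    M0 = s.df["M0"].to_numpy(float)
    totals = np.empty(n_draws)
    per_region_mean = np.zeros(len(s.df))
    for i, m in enumerate(e.models):
        sel = draws.model_idx == i
        if not sel.any():
            continue
        dnu = _region_deltas(s, m.transform)
        dd = M0 * (1.0 - np.exp(-np.outer(draws.beta[sel], dnu))) * pops
        totals[sel] = dd.sum(axis=1)
        per_region_mean += dd.sum(axis=0)
    per_region_mean /= n_draws
    mean = float(totals.mean())
    lo, hi = np.percentile(totals, [2.5, 97.5])
    baseline = s.baseline_deaths
    return ExcessDeathEstimate(
        mean=mean,
        sd=float(totals.std(ddof=1)),
        ci95=(float(lo), float(hi)),
        per_region=pd.Series(
            per_region_mean, index=s.df["region_id"].to_numpy(), name="excess_deaths"
        ),
        percent_of_baseline=100.0 * mean / baseline if baseline > 0 else float("nan"),
        draws=totals if keep_draws else None,
    )


def population_weighted_mean(concentrations, pops) -> float:
    """Population-weighted mean concentration, sum(z * pop) / sum(pop)."""
    z = np.asarray(concentrations, dtype=float)
    p = np.asarray(pops, dtype=float)
    if z.shape != p.shape:
        raise ValueError("concentrations and populations must have equal length")
    total = p.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    return float((z * p).sum() / total)
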