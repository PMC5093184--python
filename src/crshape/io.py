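"""Reading, writing and export glue for the workflow artifacts.

Cohort and scenario tables travel as comma-separated text with a header
row (UTF-8, '.' decimal); fitted models, search results and ensembles as
JSON.  JSON floats use Python's repr, so write/read round-trips are
loss-free to the full double precision (>= 15 significant digits).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cox import CohortTable, FittedRiskModel
from .ensemble import ModelEnsemble, ensemble_hr_band
from .hia import SCENARIO_COLUMNS, ExcessDeathEstimate, ScenarioTable
from .search import SearchEntry, SearchResult
from .transforms import hazard_ratio, hr_derivative

logger = logging.getLogger(__name__)

__all__ = [
    "read_cohort",
    "read_scenario",
    "write_json",
    "read_json",
    "search_result_from_dict",
    "export_curve",
    "estimate_to_dict",
    "file_digest",
]


def read_cohort(
    path,
    time_col: str,
    event_col: str,
    exposure_col: str,
    covariate_cols=(),
    strata_cols=(),
) -> CohortTable:
    """Read a delimited cohort file and bind its column roles.

    Rows with missing values in any modelled column are dropped with a
    logged count; remaining validation (positive times, binary events,
    at least one event) is delegated to :class:`CohortTable`.
    """
    df = pd.read_csv(path)
    cols = [time_col, event_col, exposure_col] + list(covariate_cols) + list(strata_cols)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    n0 = len(df)
    df = df.dropna(subset=cols)
    if len(df) < n0:
        logger.warning("%s: dropped %d rows with missing modelled values", path, n0 - len(df))
    return CohortTable(
        df.reset_index(drop=True),
        time_col,
        event_col,
        exposure_col,
        list(covariate_cols),
        list(strata_cols),
    )


def read_scenario(path) -> ScenarioTable:
    df = pd.read_csv(path)
    missing = [c for c in SCENARIO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return ScenarioTable(df)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = obj.to_dict() if hasattr(obj, "to_dict") else obj
    path.write_text(json.dumps(d, indent=2) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def search_result_from_dict(d: dict) -> SearchResult:
    fitted = [
        SearchEntry(
            f_kind=e["f_kind"],
            tau=float(e["tau"]),
            percentile=float(e["percentile"]),
            mu=float(e["mu"]),
            model=FittedRiskModel.from_dict(e["model"]),
            step=int(e["step"]),
        )
        for e in d["fitted"]
    ]
    return SearchResult(fitted=fitted, optimal=int(d["optimal"]), trace=list(d["trace"]))


def estimate_to_dict(est: ExcessDeathEstimate, seed=None, n_draws=None) -> dict:
    d = {
        "mean": est.mean,
        "sd": est.sd,
        "ci95": list(est.ci95),
        "percent_of_baseline": est.percent_of_baseline,
        "per_region": {str(k): float(v) for k, v in est.per_region.items()},
    }
    if seed is not None:
        d["seed"] = seed
    if n_draws is not None:
        d["n_draws"] = n_draws
    return d


def export_curve(
    model_or_ensemble,
    z_grid,
    z_ref: float | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate HR and dHR/dz with uncertainty bands over a grid.

    Point curves are plug-in evaluations (the weighted mixture of the
    fitted curves for an ensemble); bands are Monte-Carlo percentiles
    from the ensemble draw machinery.  The hazard ratio is anchored at
    ``z_ref`` (default: the grid minimum, the usual reporting choice of
    starting curves at the lowest observed exposure).
    """
    z_grid = np.asarray(z_grid, dtype=float)
    if z_ref is None:
        z_ref = float(z_grid.min())
    if isinstance(model_or_ensemble, FittedRiskModel):
        ens = ModelEnsemble([model_or_ensemble], np.array([1.0]))
    elif isinstance(model_or_ensemble, ModelEnsemble):
        ens = model_or_ensemble
    else:
        raise TypeError("expected a FittedRiskModel or ModelEnsemble")

    hr_point = np.zeros_like(z_grid)
    dhr_point = np.zeros_like(z_grid)
    for m, w in zip(ens.models, ens.weights):
        hr_point += w * hazard_ratio(z_grid, z_ref, m.curve)
        dhr_point += w * hr_derivative(z_grid, m.curve, z_ref=z_ref)
    band = ensemble_hr_band(ens, z_grid, z_ref, n_draws=n_draws, seed=seed)
    return pd.DataFrame(
        {
            "z": z_grid,
            "hr": hr_point,
            "hr_lower": band.hr_lo,
            "hr_upper": band.hr_hi,
            "dhr_dz": dhr_point,
            "dhr_dz_lower": band.dhr_lo,
            "dhr_dz_upper": band.dhr_hi,
        }
    )


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
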