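"""Percentile-grid search for the best-fitting transformed exposure.

The three-step procedure, designed to keep the number of Cox model runs
small:

1. Fit 16 models: mu at the 0/25/50/75th exposure percentiles, tau in
   {0.1, 0.2}, f in {z, log z}; keep the largest partial log-likelihood.
2. Holding the winning f and tau, refit with mu moved 5 percentile points
   below and above the winner.  Percentiles below the minimum extend the
   grid by multiples of the (P5 - min) increment: the "-5k-th percentile"
   is min - k * (P5 - min).
3. If neither Step-2 fit improves, stop.  Otherwise keep stepping mu in
   the improving direction (5 percentile points at a time, bounded below
   the minimum by ``max_below_min_steps`` increments) until the
   log-likelihood stops increasing.

Ties in log-likelihood within ``tie_tol`` are broken toward the larger mu
(the flatter, more conservative low-end curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox import CohortTable, FittedRiskModel, fit_transformed_cox
from .transforms import ExposureTransform

__all__ = [
    "SearchConfig",
    "SearchEntry",
    "SearchResult",
    "exposure_percentile",
    "initial_grid",
    "search",
]


@dataclass(frozen=True)
class SearchConfig:
    tau_set: tuple[float, ...] = (0.1, 0.2)
    f_set: tuple[str, ...] = ("identity", "log")
    initial_percentiles: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0)
    refine_step: float = 5.0
    percentile_method: str = "linear"
    max_below_min_steps: int = 6
    tie_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.refine_step <= 0:
            raise ValueError("refine_step must be positive")
        if any(p < 0 or p > 100 for p in self.initial_percentiles):
            raise ValueError("initial percentiles must lie in [0, 100]")


def exposure_percentile(zs, p: float, method: str = "linear") -> float:
    """The p-th sample percentile, extended below the minimum.

    For p >= 0 this is the ordinary sample percentile (linear
    interpolation between order statistics by default).  For p = -5k the
    grid is extended by whole multiples of the gap between the 5th
    percentile and the minimum: min - k * (P5 - min).
    """
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise ValueError("empty exposure sample")
    if p >= 0:
        return float(np.percentile(zs, p, method=method))
    k = -p / 5.0
    if abs(k - round(k)) > 1e-9:
        raise ValueError("below-minimum percentiles must be multiples of -5")
    zmin = float(zs.min())
    inc = float(np.percentile(zs, 5, method=method)) - zmin
    return zmin - round(k) * inc


@dataclass
class SearchEntry:
    """One model run: its grid coordinates and the fitted model."""

    f_kind: str
    tau: float
    percentile: float
    mu: float
    model: FittedRiskModel
    step: int  # 1, 2 or 3

    def to_dict(self) -> dict:
        return {
            "f_kind": self.f_kind,
            "tau": self.tau,
            "percentile": self.percentile,
            "mu": self.mu,
            "step": self.step,
            "model": self.model.to_dict(),
        }


@dataclass
class SearchResult:
    fitted: list[SearchEntry]
    optimal: int
    trace: list[str] = field(default_factory=list)

    @property
    def best(self) -> SearchEntry:
        return self.fitted[self.optimal]

    def logliks(self) -> np.ndarray:
        return np.array([e.model.loglik for e in self.fitted])

    def to_dict(self) -> dict:
        return {
            "fitted": [e.to_dict() for e in self.fitted],
            "optimal": self.optimal,
            "trace": list(self.trace),
        }


def _check_exposure(zs) -> None:
    zs = np.asarray(zs, dtype=float)
    if np.ptp(zs) <= 0:
        raise ValueError("degenerate exposure: all concentrations equal")


def initial_grid(zs, cfg: SearchConfig = SearchConfig()) -> list[tuple[str, float, float, ExposureTransform]]:
    """The Step-1 grid: (f_kind, tau, percentile, transform) tuples.

    |f_set| x |tau_set| x |initial_percentiles| transforms (16 at the
    defaults), all sharing range_r = max - min of the sample.
    """
    zs = np.asarray(zs, dtype=float)
    _check_exposure(zs)
    r = float(np.ptp(zs))
    out = []
    for f_kind in cfg.f_set:
        for tau in cfg.tau_set:
            for p in cfg.initial_percentiles:
                mu = exposure_percentile(zs, p, cfg.percentile_method)
                out.append(
                    (f_kind, tau, p, ExposureTransform(f_kind, mu=mu, tau=tau, range_r=r))
                )
    return out


def search(
    cohort: CohortTable,
    cfg: SearchConfig = SearchConfig(),
    ties: str = "efron",
    fitter=None,
) -> SearchResult:
    """Run the three-step model search on a cohort.

    ``fitter(cohort, transform, ties) -> FittedRiskModel`` defaults to
    :func:`crshape.cox.fit_transformed_cox`; it is injectable so the walk
    logic can be exercised against a synthetic likelihood surface.
    The search is deterministic given cohort and config.
    """
    if fitter is None:
        fitter = fit_transformed_cox
    zs = cohort.exposures()
    _check_exposure(zs)
    r = float(np.ptp(zs))
    min_pct = -cfg.refine_step * cfg.max_below_min_steps

    fitted: list[SearchEntry] = []
    seen: set[tuple[str, float, float]] = set()
    trace: list[str] = []

    def run(f_kind: str, tau: float, p: float, step: int) -> SearchEntry | None:
        mu = exposure_percentile(zs, p, cfg.percentile_method)
        key = (f_kind, tau, round(mu, 12))
        if key in seen:
            return None
        seen.add(key)
        t = ExposureTransform(f_kind, mu=mu, tau=tau, range_r=r)
        model = fitter(cohort, t, ties)
        entry = SearchEntry(f_kind, tau, p, mu, model, step)
        fitted.append(entry)
        trace.append(
            f"step{step}: f={f_kind} tau={tau} p={p:g} mu={mu:.6g} "
            f"loglik={model.loglik:.6f}"
        )
        return entry

    def better(a: float, b: float) -> bool:
        """a strictly improves on b (beyond the tie tolerance)."""
        return a > b + cfg.tie_tol

    def best_index() -> int:
        # max loglik; ties within tie_tol broken toward larger mu
        idx = 0
        for i in range(1, len(fitted)):
            li, lb = fitted[i].model.loglik, fitted[idx].model.loglik
            if better(li, lb) or (abs(li - lb) <= cfg.tie_tol and fitted[i].mu > fitted[idx].mu):
                idx = i
        return idx

    # Step 1: the full factorial grid
    for f_kind, tau, p, _t in initial_grid(zs, cfg):
        run(f_kind, tau, p, step=1)
    i1 = best_index()
    b1 = fitted[i1]
    trace.append(f"step1 winner: f={b1.f_kind} tau={b1.tau} p={b1.percentile:g}")

    # Step 2: neighbours of the winner, f and tau held fixed
    p0 = b1.percentile
    candidates = []
    for p in (p0 - cfg.refine_step, p0 + cfg.refine_step):
        if p > 100 or p < min_pct:
            continue
        e = run(b1.f_kind, b1.tau, p, step=2)
        if e is not None:
            candidates.append(e)
    improved = [e for e in candidates if better(e.model.loglik, b1.model.loglik)]
    if not improved:
        trace.append("step2: no improvement - stop")
        return SearchResult(fitted, best_index(), trace)

    # Step 3: walk in the improving direction until loglik stops increasing
    best_e = max(improved, key=lambda e: e.model.loglik)
    direction = np.sign(best_e.percentile - p0)
    trace.append(f"step3: walking direction {int(direction):+d}")
    current = best_e
    while True:
        p_next = current.percentile + direction * cfg.refine_step
        if p_next > 100 or p_next < min_pct:
            trace.append("step3: grid boundary reached")
            break
        e = run(b1.f_kind, b1.tau, p_next, step=3)
        if e is None:  # already fitted: walk would revisit, stop
            trace.append("step3: revisit avoided - stop")
            break
        if not better(e.model.loglik, current.model.loglik):
            trace.append("step3: no further improvement - stop")
            break
        current = e
    return SearchResult(fitted, best_index(), trace)
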