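"""Random-effects pooling of excess-death distributions across studies.

Each study's Monte-Carlo excess-death distribution is reduced to a normal
summary (mean, se); studies are then combined by DerSimonian-Laird
random-effects meta-analysis, which admits true between-study
heterogeneity tau2 on top of within-study error.  Pooling the burden
distributions rather than the risk curves themselves keeps the target
quantity (attributable deaths) common across studies even when the fitted
concentration-response shapes differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .hia import ExcessDeathEstimate

__all__ = ["NormalSummary", "PooledEstimate", "normal_summary", "random_effects_pool"]

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class NormalSummary:
    """Normal approximation of one study's excess-death distribution."""

    mean: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError("se must be positive")


def normal_summary(est=None, *, mean=None, lower=None, upper=None) -> NormalSummary:
    """Summarise an estimate, or a printed (mean, 95% CI) triple.

    From retained draws: empirical mean and sd.  From a printed interval:
    se = (upper - lower) / (2 * 1.96), the normal-theory back-calculation.
    """
    if est is not None:
        if isinstance(est, ExcessDeathEstimate):
            if est.draws is not None:
                return NormalSummary(float(np.mean(est.draws)), float(np.std(est.draws, ddof=1)))
            return NormalSummary(est.mean, est.sd)
        raise TypeError("est must be an ExcessDeathEstimate")
    if mean is None or lower is None or upper is None:
        raise ValueError("provide either an estimate or a (mean, lower, upper) triple")
    if upper <= lower:
        raise ValueError("upper must exceed lower")
    return NormalSummary(float(mean), float(upper - lower) / (2.0 * Z975))


@dataclass(frozen=True)
class PooledEstimate:
    mean: float
    se: float
    tau2: float
    ci95: tuple[float, float]
    k: int

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    ybar = (w * y).sum() / w.sum()
    Q = (w * (y - ybar) ** 2).sum()
    k = len(y)
    denom = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (Q - (k - 1)) / denom)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    def neg_restricted_ll(log_t2):
        t2 = np.exp(log_t2)
        w = 1.0 / (v + t2)
        mu = (w * y).sum() / w.sum()
        return 0.5 * (
            np.log(v + t2).sum() + np.log(w.sum()) + (w * (y - mu) ** 2).sum()
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(np.log(1e-12 * v.mean()), np.log(1e6 * v.mean())),
        method="bounded",
    )
    t2 = float(np.exp(res.x))
    return 0.0 if t2 < 1e-10 * v.mean() else t2


def random_effects_pool(summaries, method: str = "dl") -> PooledEstimate:
    """Random-effects pooled mean of k >= 2 normal study summaries.

    DerSimonian-Laird by default: tau2 from the Q statistic with
    fixed-effect weights 1/se_i^2, then pooled mean and se under weights
    1/(se_i^2 + tau2).  ``method="reml"`` estimates tau2 by restricted
    maximum likelihood instead.  The 95% interval uses normal quantiles.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("pooling requires at least two studies")
    y = np.array([s.mean for s in summaries], dtype=float)
    v = np.array([s.se**2 for s in summaries], dtype=float)
    if np.any(v <= 0):
        raise ValueError("non-positive study variance")
    if method == "dl":
        tau2 = _dl_tau2(y, v)
    elif method == "reml":
        tau2 = _reml_tau2(y, v)
    else:
        raise ValueError(f"unknown method {method!r}")
    wstar = 1.0 / (v + tau2)
    mean = float((wstar * y).sum() / wstar.sum())
    se = float(wstar.sum() ** -0.5)
    return PooledEstimate(
        mean=mean,
        se=se,
        tau2=float(tau2),
        ci95=(mean - Z975 * se, mean + Z975 * se),
        k=len(summaries),
    )
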