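"""Likelihood-weighted model averaging over the fitted curve family.

Every model fit during the search enters an ensemble with normalized
likelihood weights w_i = exp(LL_i - max LL) / sum_j exp(LL_j - max LL),
as in Bayesian model averaging with equal parameter counts.  Joint
(model, beta) uncertainty is propagated by Monte Carlo: a model index is
drawn with probability equal to its weight and beta from N(beta_hat_i,
se_i) conditional on the model.  Hazard-ratio and derivative uncertainty
bands are pointwise percentiles across draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox import FittedRiskModel
from .transforms import RiskCurve, hazard_ratio, hr_derivative, transform_value

__all__ = [
    "ModelEnsemble",
    "CurveDrawSet",
    "HRBand",
    "likelihood_weights",
    "sample_curves",
    "ensemble_hr_band",
]


def likelihood_weights(logliks) -> np.ndarray:
    """Normalized likelihood weights from partial log-likelihoods.

    Max-subtraction makes the softmax stable for log-likelihoods of any
    magnitude (cohort-scale values are around -3e6); the result is
    invariant to adding a constant to every log-likelihood.
    """
    ll = np.asarray(logliks, dtype=float)
    if ll.size == 0:
        raise ValueError("no log-likelihoods supplied")
    m = np.max(ll)
    if not np.isfinite(m):
        raise ValueError("all log-likelihoods are non-finite")
    w = np.exp(ll - m)
    return w / w.sum()


@dataclass
class ModelEnsemble:
    """Fitted models with their normalized likelihood weights.

    ``report_threshold`` hides negligible-weight models from reports only;
    every model always participates in weighting and sampling (dropping
    them would bias the mixture).
    """

    models: list[FittedRiskModel]
    weights: np.ndarray
    report_threshold: float = 0.001

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.models) != len(self.weights):
            raise ValueError("one weight per model required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_models(cls, models, report_threshold: float = 0.001) -> "ModelEnsemble":
        w = likelihood_weights([m.loglik for m in models])
        return cls(list(models), w, report_threshold)

    @classmethod
    def from_search(cls, result, report_threshold: float = 0.001) -> "ModelEnsemble":
        return cls.from_models([e.model for e in result.fitted], report_threshold)

    def reported(self) -> list[tuple[FittedRiskModel, float]]:
        """(model, weight) pairs above the report threshold."""
        return [
            (m, float(w))
            for m, w in zip(self.models, self.weights)
            if w >= self.report_threshold
        ]

    def to_dict(self) -> dict:
        return {
            "models": [m.to_dict() for m in self.models],
            "weights": self.weights.tolist(),
            "report_threshold": self.report_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEnsemble":
        return cls(
            [FittedRiskModel.from_dict(m) for m in d["models"]],
            np.asarray(d["weights"], dtype=float),
            float(d.get("report_threshold", 0.001)),
        )


@dataclass
class CurveDrawSet:
    """Monte-Carlo draws of (model index, beta realization)."""

    model_idx: np.ndarray
    beta: np.ndarray
    seed: int
    n_draws: int


def sample_curves(e: ModelEnsemble, n_draws: int, seed: int) -> CurveDrawSet:
    """Draw (model, beta) pairs from the ensemble mixture.

    Model i is selected with probability w_i; conditional on the model,
    beta ~ N(beta_hat_i, se_i).  Reproducible under ``seed``.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(e.models), size=n_draws, p=e.weights)
    bhat = np.array([m.beta_hat for m in e.models])
    se = np.array([m.se_beta for m in e.models])
    beta = rng.normal(bhat[idx], se[idx])
    return CurveDrawSet(model_idx=idx, beta=beta, seed=seed, n_draws=n_draws)


@dataclass
class HRBand:
    """Pointwise summary curves over a concentration grid."""

    z: np.ndarray
    hr_mean: np.ndarray
    hr_lo: np.ndarray
    hr_hi: np.ndarray
    dhr_mean: np.ndarray
    dhr_lo: np.ndarray
    dhr_hi: np.ndarray


def ensemble_hr_band(
    e: ModelEnsemble,
    z_grid,
    z_ref: float,
    n_draws: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> HRBand:
    """Pointwise mean and (alpha/2, 1-alpha/2) percentile curves.

    Both the hazard ratio HR(z)/HR(z_ref) and its concentration
    derivative are summarised from the same draw set, so the two bands
    are coherent.  Draws are grouped by model so each transform is
    evaluated on the grid once.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    draws = sample_curves(e, n_draws, seed)
    hr = np.empty((n_draws, z_grid.size))
    dhr = np.empty((n_draws, z_grid.size))
    for i, m in enumerate(e.models):
        sel = draws.model_idx == i
        if not sel.any():
            continue
        t = m.transform
        dnu = transform_value(z_grid, t) - transform_value(z_ref, t)
        from .transforms import transform_derivative

        nup = transform_derivative(z_grid, t)
        b = draws.beta[sel][:, None]
        hr[sel] = np.exp(b * dnu[None, :])
        dhr[sel] = b * nup[None, :] * hr[sel]
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    return HRBand(
        z=z_grid,
        hr_mean=hr.mean(axis=0),
        hr_lo=np.percentile(hr, lo, axis=0),
        hr_hi=np.percentile(hr, hi, axis=0),
        dhr_mean=dhr.mean(axis=0),
        dhr_lo=np.percentile(dhr, lo, axis=0),
        dhr_hi=np.percentile(dhr, hi, axis=0),
    )
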