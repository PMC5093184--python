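"""Stratified Cox partial-likelihood estimation with a transformed exposure.

The exposure enters as the fixed covariate nu(z | mu, tau) = f(z) * omega(z)
computed by :mod:`crshape.transforms`; adjustment covariates get their own
coefficients (gamma), and the baseline hazard is eliminated per stratum by
the partial likelihood.  Estimation is Newton-Raphson on the exact
stratified partial log-likelihood with either Efron or Breslow handling of
tied event times; standard errors come from the inverse observed
information at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import ExposureTransform, RiskCurve, transform_value

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "FittedRiskModel",
    "PartialLikelihood",
    "fit_transformed_cox",
    "partial_loglik",
    "ConvergenceError",
    "DegenerateCovariateError",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration budget."""


class DegenerateCovariateError(ValueError):
    """The transformed exposure is constant within every analysed stratum."""


@dataclass
class CohortTable:
    """A validated cohort: one row per subject.

    Wraps a DataFrame with explicit column roles.  Times must be positive,
    events binary, and no modelled column may contain missing values.
    """

    df: pd.DataFrame
    time_col: str
    event_col: str
    exposure_col: str
    covariate_cols: list[str] = field(default_factory=list)
    strata_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = (
            [self.time_col, self.event_col, self.exposure_col]
            + list(self.covariate_cols)
            + list(self.strata_cols)
        )
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort is missing columns: {missing}")
        modelled = self.df[cols]
        if modelled.isna().any().any():
            bad = modelled.columns[modelled.isna().any()].tolist()
            raise ValueError(f"missing values in modelled columns: {bad}")
        t = self.df[self.time_col].to_numpy(dtype=float)
        if np.any(t <= 0):
            row = int(np.argmax(t <= 0))
            raise ValueError(f"non-positive follow-up time at row {row}")
        ev = self.df[self.event_col].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if int(ev.sum()) == 0:
            raise ValueError("cohort contains no events")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df[self.event_col].sum())

    def times(self) -> np.ndarray:
        return self.df[self.time_col].to_numpy(dtype=float)

    def events(self) -> np.ndarray:
        return self.df[self.event_col].to_numpy(dtype=int)

    def exposures(self) -> np.ndarray:
        return self.df[self.exposure_col].to_numpy(dtype=float)

    def covariates(self) -> np.ndarray:
        if not self.covariate_cols:
            return np.empty((self.n, 0))
        return self.df[list(self.covariate_cols)].to_numpy(dtype=float)

    def stratum_codes(self) -> np.ndarray:
        """Integer code of the cross-classification of the strata columns."""
        if not self.strata_cols:
            return np.zeros(self.n, dtype=np.int64)
        key = pd.MultiIndex.from_frame(self.df[list(self.strata_cols)])
        return key.factorize()[0].astype(np.int64)


@dataclass(frozen=True)
class FittedRiskModel:
    """A fitted member of the curve family.

    Holds the transform, beta-hat with its standard error from the observed
    information, the adjustment-covariate estimates, and the partial
    log-likelihood at the optimum (the quantity the model search and the
    ensemble weights operate on).
    """

    transform: ExposureTransform
    beta_hat: float
    se_beta: float
    gamma_hat: tuple[float, ...]
    loglik: float
    n_events: int
    ties: str = "efron"

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise ValueError("loglik must be finite")
        if not (self.se_beta > 0):
            raise ValueError("se_beta must be positive")

    @property
    def curve(self) -> RiskCurve:
        return RiskCurve(self.transform, self.beta_hat)

    def to_dict(self) -> dict:
        d = self.transform.to_dict()
        d.update(
            beta=self.beta_hat,
            se_beta=self.se_beta,
            gamma=list(self.gamma_hat),
            loglik=self.loglik,
            n_events=self.n_events,
            ties=self.ties,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRiskModel":
        return cls(
            transform=ExposureTransform.from_dict(d),
            beta_hat=float(d["beta"]),
            se_beta=float(d["se_beta"]),
            gamma_hat=tuple(float(g) for g in d.get("gamma", [])),
            loglik=float(d["loglik"]),
            n_events=int(d.get("n_events", 0)),
            ties=d.get("ties", "efron"),
        )


class PartialLikelihood:
    """Exact stratified Cox partial log-likelihood, gradient and Hessian.

    Rows are sorted by stratum and descending time once at construction;
    risk-set sums are then prefix sums.  Tied event times within a stratum
    form a single group; under Efron the d tied events see denominators
    S0 - (l/d) * S0_D for l = 0..d-1, under Breslow all d see S0.  The
    expansion over l is vectorised (one row per event), so untied data pay
    no penalty and the two conventions coincide there.
    """

    def __init__(self, times, events, X, strata=None, ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
        self.ties = ties
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = len(times)
        if strata is None:
            strata = np.zeros(n, dtype=np.int64)
        strata = np.asarray(strata)

        # Drop strata without events: they contribute nothing.
        codes, inv = np.unique(strata, return_inverse=True)
        ev_per = np.bincount(inv, weights=events)
        keep_code = ev_per > 0
        if not keep_code.all():
            n_drop = int((~keep_code[inv]).sum())
            logger.warning(
                "dropping %d strata (%d subjects) with zero events",
                int((~keep_code).sum()),
                n_drop,
            )
        keep = keep_code[inv]
        times, events, X, inv = times[keep], events[keep], X[keep], inv[keep]

        order = np.lexsort((-times, inv))
        self.times = times[order]
        self.events = events[order]
        self.X = X[order]
        self.strata = inv[order]
        self.n, self.p = self.X.shape
        self.n_events = int(self.events.sum())

        # Group rows by (stratum, time); risk set of a group = stratum
        # prefix up to and including the group (descending-time order).
        key = np.empty((self.n, 2))
        key[:, 0] = self.strata
        key[:, 1] = -self.times
        change = np.ones(self.n, dtype=bool)
        change[1:] = np.any(key[1:] != key[:-1], axis=1)
        self.group_start = np.flatnonzero(change)
        self.group_end = np.append(self.group_start[1:], self.n)  # exclusive

        strat_change = np.ones(self.n, dtype=bool)
        strat_change[1:] = self.strata[1:] != self.strata[:-1]
        strat_start = np.flatnonzero(strat_change)
        # stratum start index for each group
        self.group_strat_start = strat_start[
            np.searchsorted(strat_start, self.group_start, side="right") - 1
        ]

        # event groups and the tied-event membership within each
        ev_count = np.add.reduceat(self.events, self.group_start)
        if self.group_start[-1] == self.n:  # reduceat quirk, cannot happen here
            pass
        self.event_groups = np.flatnonzero(ev_count > 0)
        self.d = ev_count[self.event_groups].astype(np.int64)
        self.event_rows = np.flatnonzero(self.events == 1)
        # expansion: for event group g with d_g events, fractions l/d_g
        l = np.concatenate([np.arange(di) for di in self.d]) if len(self.d) else np.array([])
        if self.ties == "efron":
            self.frac = l / np.repeat(self.d, self.d)
        else:
            self.frac = np.zeros_like(l, dtype=float)
        self.rep = np.repeat(np.arange(len(self.event_groups)), self.d)

    def _risk_sums(self, arr):
        """Prefix sums of arr (n x k) over each event group's risk set."""
        cs = np.cumsum(arr, axis=0)
        ge = self.group_end[self.event_groups] - 1
        ss = self.group_strat_start[self.event_groups]
        out = cs[ge]
        nz = ss > 0
        out[nz] -= cs[ss[nz] - 1]
        return out

    def _tied_sums(self, arr):
        """Sums of arr over the tied event rows of each event group."""
        ev = self.events.astype(bool)
        arr_ev = arr[ev]
        # event rows, grouped: cumulative counts of events per group
        grp_of_event = np.searchsorted(self.group_end, self.event_rows, side="right")
        # map group index -> position in event_groups
        pos = np.searchsorted(self.event_groups, grp_of_event)
        k = arr.shape[1]
        out = np.zeros((len(self.event_groups), k))
        np.add.at(out, pos, arr_ev)
        return out

    def loglik_grad_hess(self, params, want=3):
        b = np.asarray(params, dtype=float)
        eta = self.X @ b
        # guard against overflow during line search
        w = np.exp(np.clip(eta, -700, 700))
        p = self.p

        cols = [w[:, None], w[:, None] * self.X]
        if want >= 3:
            xx = (self.X[:, :, None] * self.X[:, None, :]).reshape(self.n, p * p)
            cols.append(w[:, None] * xx)
        arr = np.concatenate(cols, axis=1)
        R = self._risk_sums(arr)
        D = self._tied_sums(arr)

        S0 = R[:, 0][self.rep] - self.frac * D[:, 0][self.rep]
        ll = float(eta[self.event_rows].sum() - np.log(S0).sum())
        if want == 1:
            return ll, None, None

        S1 = R[:, 1 : 1 + p][self.rep] - self.frac[:, None] * D[:, 1 : 1 + p][self.rep]
        Ebar = S1 / S0[:, None]
        grad = self.X[self.event_rows].sum(axis=0) - Ebar.sum(axis=0)
        if want == 2:
            return ll, grad, None

        S2 = (
            R[:, 1 + p :][self.rep] - self.frac[:, None] * D[:, 1 + p :][self.rep]
        ).reshape(-1, p, p)
        V = S2 / S0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :]
        hess = -V.sum(axis=0)
        return ll, grad, hess

    def loglik(self, params) -> float:
        return self.loglik_grad_hess(params, want=1)[0]

    def fit(self, init=None, tol: float = 1e-9, max_iter: int = 100):
        """Newton-Raphson with step-halving.

        Returns (params, loglik, covariance).  Convergence: relative
        log-likelihood change below ``tol``.
        """
        b = np.zeros(self.p) if init is None else np.asarray(init, dtype=float)
        ll, g, H = self.loglik_grad_hess(b)
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError as exc:
                raise DegenerateCovariateError(
                    "singular information matrix (constant covariate within strata?)"
                ) from exc
            scale = 1.0
            for _half in range(40):
                b_new = b + scale * step
                ll_new = self.loglik(b_new)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            else:
                raise ConvergenceError(
                    f"step-halving failed at loglik={ll:.6g}, |grad|={np.abs(g).max():.3g}"
                )
            rel = abs(ll_new - ll) / (abs(ll) + 1.0)
            b, ll = b_new, ll_new
            ll, g, H = self.loglik_grad_hess(b)
            if rel < tol and np.abs(g).max() < 1e-5 * (self.n_events + 1):
                cov = np.linalg.inv(-H)
                return b, ll, cov
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (loglik={ll:.6g}, "
            f"|grad|max={np.abs(g).max():.3g})"
        )


def _design(cohort: CohortTable, t: ExposureTransform):
    nu = transform_value(cohort.exposures(), t)
    X = np.column_stack([nu, cohort.covariates()])
    return X


def fit_transformed_cox(
    cohort: CohortTable, t: ExposureTransform, ties: str = "efron"
) -> FittedRiskModel:
    """Fit the stratified Cox model with covariate nu(z | mu, tau).

    The transformed exposure is the first model column; adjustment
    covariates follow.  Raises :class:`DegenerateCovariateError` if the
    transformed exposure is constant within every analysed stratum.
    """
    X = _design(cohort, t)
    strata = cohort.stratum_codes()
    # degenerate-exposure check within event-bearing strata
    nu = X[:, 0]
    ev_strata = np.unique(strata[cohort.events() == 1])
    spread = max(
        (np.ptp(nu[strata == s]) for s in ev_strata),
        default=0.0,
    )
    if spread < 1e-12 * (1.0 + np.abs(nu).max()):
        raise DegenerateCovariateError(
            "transformed exposure is constant within every stratum"
        )
    pl = PartialLikelihood(cohort.times(), cohort.events(), X, strata, ties=ties)
    params, ll, cov = pl.fit()
    se = float(np.sqrt(cov[0, 0]))
    return FittedRiskModel(
        transform=t,
        beta_hat=float(params[0]),
        se_beta=se,
        gamma_hat=tuple(float(v) for v in params[1:]),
        loglik=ll,
        n_events=pl.n_events,
        ties=ties,
    )


def partial_loglik(
    cohort: CohortTable,
    t: ExposureTransform,
    beta: float,
    gamma=(),
    ties: str = "efron",
) -> float:
    """Stratified Cox partial log-likelihood at given (beta, gamma)."""
    X = _design(cohort, t)
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float)) if len(np.atleast_1d(gamma)) else np.empty(0)
    params = np.concatenate([[float(beta)], gamma])
    if params.shape[0] != X.shape[1]:
        raise ValueError(
            f"expected {X.shape[1] - 1} gamma coefficients, got {params.shape[0] - 1}"
        )
    pl = PartialLikelihood(
        cohort.times(), cohort.events(), X, cohort.stratum_codes(), ties=ties
    )
    return pl.loglik(params)
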