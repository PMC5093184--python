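"""Logistic-weighted exposure transforms and the hazard-ratio curve family.

The concentration-response family is built from a logistic weighting
function

    omega(z | mu, tau) = 1 / (1 + exp(-(z - mu) / (tau * r)))

applied multiplicatively to a monotone base transform f(z), either the
identity (optionally shifted, f(z) = z - T, for threshold shapes) or the
natural logarithm.  The transformed exposure

    nu(z) = f(z) * omega(z | mu, tau)

enters a Cox relative-risk model as a single fixed covariate with
coefficient beta, so the log hazard ratio between two concentrations is
beta * (nu(z1) - nu(z2)).  mu locates the sigmoid, tau controls its
curvature relative to the exposure range r: tau <= 0.001 approximates an
indicator (threshold) at mu, tau = 0.1 gives gently sigmoidal shapes,
tau = 0.2 approximates power-of-concentration curves, and a very large
negative mu recovers the plain linear or log-linear model (omega ~ 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExposureTransform",
    "RiskCurve",
    "logistic_weight",
    "transform_value",
    "transform_derivative",
    "delta_nu",
    "hazard_ratio",
    "hr_derivative",
    "make_special",
]

# exp() overflows float64 just above 709; clipping the logistic exponent at
# +/-700 keeps omega exact to machine precision at the saturated ends.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class ExposureTransform:
    """A member of the curve family: f-kind, location mu, curvature tau.

    Parameters
    ----------
    f_kind
        Base transform: ``"identity"`` (f(z) = z - f_shift) or ``"log"``
        (natural log of raw concentration; z must be > 0).
    mu
        Location of the logistic weight, in concentration units (ug/m3).
        May be negative (below the observed minimum).
    tau
        Positive curvature scalar; the logistic scale is tau * range_r.
    range_r
        Span (max - min) of the analytic sample's exposure, stored with
        the transform so a fitted model is portable to new populations.
    f_shift
        Subtracted from z before weighting when f_kind is "identity";
        non-zero only for threshold shapes (f(z) = z - T).
    """

    f_kind: str
    mu: float
    tau: float
    range_r: float
    f_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.f_kind not in ("identity", "log"):
            raise ValueError(f"unknown f_kind {self.f_kind!r}")
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not np.isfinite(self.range_r) or self.range_r <= 0:
            raise ValueError(f"range_r must be positive, got {self.range_r}")
        if self.f_kind == "log" and self.f_shift != 0.0:
            raise ValueError("f_shift is only meaningful for f_kind='identity'")

    def f(self, z):
        z = np.asarray(z, dtype=float)
        if self.f_kind == "log":
            if np.any(z <= 0):
                raise ValueError("f_kind='log' requires strictly positive concentrations")
            return np.log(z)
        return z - self.f_shift

    def f_prime(self, z):
        z = np.asarray(z, dtype=float)
        if self.f_kind == "log":
            if np.any(z <= 0):
                raise ValueError("f_kind='log' requires strictly positive concentrations")
            return 1.0 / z
        return np.ones_like(z)

    def to_dict(self) -> dict:
        return {
            "f_kind": self.f_kind,
            "mu": self.mu,
            "tau": self.tau,
            "range_r": self.range_r,
            "f_shift": self.f_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExposureTransform":
        return cls(
            f_kind=d["f_kind"],
            mu=float(d["mu"]),
            tau=float(d["tau"]),
            range_r=float(d["range_r"]),
            f_shift=float(d.get("f_shift", 0.0)),
        )


@dataclass(frozen=True)
class RiskCurve:
    """An exposure transform together with its log-hazard coefficient."""

    transform: ExposureTransform
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


def logistic_weight(z, t: ExposureTransform):
    """Logistic weight omega(z | mu, tau) in the open interval (0, 1).

    Strictly increasing in z; equals 1/2 at z = mu.  The scale of the
    sigmoid is tau * range_r, so tau is unitless curvature relative to
    the exposure span.
    """
    z = np.asarray(z, dtype=float)
    expo = np.clip(-(z - t.mu) / (t.tau * t.range_r), -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + np.exp(expo))


def transform_value(z, t: ExposureTransform):
    """Transformed exposure nu(z) = f(z) * omega(z | mu, tau)."""
    return t.f(z) * logistic_weight(z, t)


def transform_derivative(z, t: ExposureTransform):
    """d nu / d z = f'(z) omega(z) + f(z) omega(z)(1 - omega(z)) / (tau r)."""
    w = logistic_weight(z, t)
    return t.f_prime(z) * w + t.f(z) * w * (1.0 - w) / (t.tau * t.range_r)


def delta_nu(zC, zF, t: ExposureTransform):
    """Transformed change in exposure, nu(zC) - nu(zF).

    Antisymmetric in its arguments; multiplied by beta it is the log of
    the hazard ratio between the two concentrations.
    """
    return transform_value(zC, t) - transform_value(zF, t)


def hazard_ratio(z, z_ref, c: RiskCurve):
    """HR(z) / HR(z_ref) = exp(beta * (nu(z) - nu(z_ref)))."""
    return np.exp(c.beta * delta_nu(z, z_ref, c.transform))


def hr_derivative(z, c: RiskCurve, z_ref=None):
    """Slope of the hazard-ratio curve with respect to concentration.

    Analytically beta * nu'(z) * exp(beta * (nu(z) - nu(z_ref))).  With
    ``z_ref=None`` the curve is left unanchored (reference where nu = 0);
    anchoring only rescales the derivative by a constant factor.
    """
    nu = transform_value(z, c.transform)
    if z_ref is not None:
        nu = nu - transform_value(z_ref, c.transform)
    return c.beta * transform_derivative(z, c.transform) * np.exp(c.beta * nu)


def make_special(
    kind: str,
    z_min: float,
    z_max: float,
    threshold: float | None = None,
    mu: float | None = None,
) -> ExposureTransform:
    """Construct the named special-case transforms of the family.

    kinds
    -----
    linear
        f(z) = z with mu far below the observed range so omega ~ 1
        everywhere: the ordinary linear-in-concentration Cox covariate.
    loglinear
        f(z) = log z, same saturated weight: the log-concentration model.
    threshold
        f(z) = z - T with omega an indicator at mu = T (tau = 0.001):
        no association below T, linear above.
    power_like
        f(z) = log z with tau = 0.2: HR(z) ~ z^(beta * omega(z)), an
        approximate power of concentration; requires ``mu``.
    """
    r = float(z_max) - float(z_min)
    if r <= 0:
        raise ValueError("z_max must exceed z_min")
    # mu = min - 1e3 * r drives omega above 1 - 1e-6 over any plausible
    # range while the clipped exponent stays finite.
    far_below = float(z_min) - 1e3 * r
    if kind == "linear":
        return ExposureTransform("identity", mu=far_below, tau=0.1, range_r=r)
    if kind == "loglinear":
        return ExposureTransform("log", mu=far_below, tau=0.1, range_r=r)
    if kind == "threshold":
        if threshold is None:
            raise ValueError("threshold kind requires a threshold concentration T")
        if not (z_min <= threshold <= z_max):
            raise ValueError("threshold T must lie inside the observed range")
        return ExposureTransform(
            "identity", mu=float(threshold), tau=0.001, range_r=r, f_shift=float(threshold)
        )
    if kind == "power_like":
        if mu is None:
            raise ValueError("power_like kind requires mu")
        return ExposureTransform("log", mu=float(mu), tau=0.2, range_r=r)
    raise ValueError(f"unknown special kind {kind!r}")
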