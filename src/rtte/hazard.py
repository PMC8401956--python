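"""Parametric hazard families with multiplicative covariate and frailty effects.

Three baseline families are supported, all parameterised by a scale
``theta1`` (hazard per week) and, for the time-varying families, a shape
``theta2``:

========== =======================================
constant   h0(t) = theta1
gompertz   h0(t) = theta1 * exp(theta2 * t)
weibull    h0(t) = theta1 * t ** theta2
========== =======================================

The subject-level hazard is

    h(t | x, eta) = h0(t) * exp(eta) * exp(sum_k coef_k * (x_k - center_k)),

where ``eta`` is a normally distributed frailty deviate (variance
``omega2``) acting multiplicatively on the scale parameter, and covariates
enter through a log-linear term.  Continuous covariates are centred on a
reference value (typically the cohort median) so that ``theta1`` is the
scale for a reference subject; indicator covariates use ``center = 0``.

Cumulative hazards have closed forms in every family, which the likelihood,
simulator and survival function all use.  The Weibull hazard at ``t = 0``
is 0 for ``theta2 > 0``, ``theta1`` for ``theta2 == 0`` and undefined
(raises) for ``theta2 < 0``; its cumulative hazard is integrable near zero
whenever ``theta2 > -1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FAMILIES",
    "HazardParameters",
    "CovariateEffect",
    "HazardModel",
    "hazard",
    "cumulative_hazard",
    "survival",
    "hazard_ratio",
]

FAMILIES = ("constant", "gompertz", "weibull")

# Below this value of |theta2| the Gompertz family is evaluated through its
# constant-hazard limit to avoid catastrophic cancellation in expm1/theta2.
_GOMPERTZ_EPS = 1e-12


@dataclass(frozen=True)
class HazardParameters:
    """Baseline hazard family and its scale/shape parameters."""

    family: str
    theta1: float
    theta2: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown hazard family {self.family!r}; expected one of {FAMILIES}")
        if not np.isfinite(self.theta1) or self.theta1 <= 0:
            raise ValueError(f"theta1 must be positive and finite, got {self.theta1}")
        if self.family == "constant":
            if self.theta2 is not None:
                raise ValueError("constant hazard takes no shape parameter")
        else:
            if self.theta2 is None or not np.isfinite(self.theta2):
                raise ValueError(f"{self.family} hazard requires a finite shape parameter")
            if self.family == "weibull" and self.theta2 <= -1:
                raise ValueError("weibull shape must exceed -1 for an integrable hazard")


@dataclass(frozen=True)
class CovariateEffect:
    """Log-linear covariate effect: multiplies the hazard by exp(coef*(x - center))."""

    name: str
    coef: float
    center: float = 0.0


@dataclass(frozen=True)
class HazardModel:
    """Hazard family plus covariate effects and frailty variance."""

    params: HazardParameters
    effects: tuple[CovariateEffect, ...] = field(default_factory=tuple)
    omega2: float = 0.0

    def __post_init__(self) -> None:
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate covariate effect names: {names}")
        if self.omega2 < 0 or not np.isfinite(self.omega2):
            raise ValueError(f"frailty variance omega2 must be >= 0, got {self.omega2}")

    @property
    def family(self) -> str:
        return self.params.family

    def linear_predictor(self, cov: Mapping[str, float] | None) -> float:
        """Sum of coef*(x - center) over effects; raises if a covariate is missing."""
        if not self.effects:
            return 0.0
        if cov is None:
            raise ValueError("model has covariate effects but no covariate values were given")
        total = 0.0
        for eff in self.effects:
            try:
                x = cov[eff.name]
            except KeyError:
                raise ValueError(f"missing covariate {eff.name!r}") from None
            total += eff.coef * (x - eff.center)
        return total

    @property
    def iiv_pct(self) -> float:
        """Inter-individual variability reported as 100*sqrt(omega2)."""
        return 100.0 * float(np.sqrt(self.omega2))


# ---------------------------------------------------------------------------
# baseline family primitives (vectorised over time arguments)
# ---------------------------------------------------------------------------

def base_hazard(family: str, theta1: float, theta2: float | None, t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if family == "constant":
        return np.broadcast_to(np.float64(theta1), t.shape).copy()
    if family == "gompertz":
        return theta1 * np.exp(theta2 * t)
    # weibull: t**theta2, with 0**0 == 1 so theta2 == 0 degrades to constant
    if theta2 < 0 and np.any(t == 0):
        raise ValueError("weibull hazard with negative shape is unbounded at t = 0")
    with np.errstate(divide="ignore"):
        return theta1 * np.power(t, theta2)


def base_log_hazard(family: str, theta1: float, theta2: float | None, t):
    """log h0(t); events are clamped away from 0 before this is called."""
    t = np.asarray(t, dtype=float)
    if family == "constant":
        return np.full(t.shape, np.log(theta1))
    if family == "gompertz":
        return np.log(theta1) + theta2 * t
    return np.log(theta1) + theta2 * np.log(t)


def base_cumulative_hazard(family: str, theta1: float, theta2: float | None, t0, t1):
    """Closed-form integral of h0 over [t0, t1] (elementwise)."""
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if family == "constant":
        return theta1 * (t1 - t0)
    if family == "gompertz":
        if abs(theta2) < _GOMPERTZ_EPS:
            return theta1 * (t1 - t0)
        # theta1/theta2 * (e^{b t1} - e^{b t0}), written via expm1 for stability
        return (theta1 / theta2) * np.exp(theta2 * t0) * np.expm1(theta2 * (t1 - t0))
    p = theta2 + 1.0
    return theta1 * (np.power(t1, p) - np.power(t0, p)) / p


def base_inverse_cumulative_hazard(family: str, theta1: float, theta2: float | None, t0, target):
    """Solve H0(t0, t) = target for t (elementwise); inf where unreachable."""
    t0 = np.asarray(t0, dtype=float)
    target = np.asarray(target, dtype=float)
    if family == "constant":
        return t0 + target / theta1
    if family == "gompertz":
        if abs(theta2) < _GOMPERTZ_EPS:
            return t0 + target / theta1
        arg = (theta2 / theta1) * target * np.exp(-theta2 * t0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = t0 + np.log1p(arg) / theta2
        # negative shape: cumulative hazard is bounded; beyond the bound no event
        return np.where(arg <= -1.0, np.inf, out)
    p = theta2 + 1.0
    return np.power(np.power(t0, p) + p * target / theta1, 1.0 / p)


# ---------------------------------------------------------------------------
# model-level API
# ---------------------------------------------------------------------------

def hazard(model: HazardModel, t, cov: Mapping[str, float] | None = None, eta: float = 0.0):
    """Hazard rate h(t | cov, eta) in events per week."""
    lp = model.linear_predictor(cov)
    h = base_hazard(model.family, model.params.theta1, model.params.theta2, t)
    return h * np.exp(eta + lp)


def cumulative_hazard(model: HazardModel, t0, t1, cov: Mapping[str, float] | None = None,
                      eta: float = 0.0):
    """Integral of the hazard over [t0, t1] (dimensionless)."""
    t0a = np.asarray(t0, dtype=float)
    t1a = np.asarray(t1, dtype=float)
    if np.any(t0a < 0):
        raise ValueError("interval start must be non-negative")
    if np.any(t1a < t0a):
        raise ValueError("interval end must not precede its start")
    lp = model.linear_predictor(cov)
    h = base_cumulative_hazard(model.family, model.params.theta1, model.params.theta2, t0a, t1a)
    return h * np.exp(eta + lp)


def survival(model: HazardModel, t, cov: Mapping[str, float] | None = None, eta: float = 0.0):
    """S(t) = exp(-H(0, t)): probability of no event in (0, t]."""
    return np.exp(-cumulative_hazard(model, 0.0, t, cov=cov, eta=eta))


def hazard_ratio(effect: CovariateEffect | float, delta: float = 1.0) -> float:
    """Hazard ratio exp(coef * delta) for a change of ``delta`` covariate units."""
    coef = effect.coef if isinstance(effect, CovariateEffect) else float(effect)
    return float(np.exp(coef * delta))
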