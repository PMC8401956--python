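"""Independent oracles used by the tests.

These deliberately avoid the closed-form code paths they check: cumulative
hazards are integrated by adaptive quadrature, marginal likelihoods by
adaptive Gauss-Hermite quadrature centred at a numerically located mode,
and Kaplan-Meier curves come from lifelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from rtte.data import SubjectHistory
from rtte.hazard import HazardModel, hazard


def quad_cumhaz(model: HazardModel, t0: float, t1: float,
                cov=None, eta: float = 0.0, epsrel: float = 1e-11) -> float:
    """Adaptive quadrature of the hazard over [t0, t1]."""
    val, _ = quad(lambda u: float(hazard(model, u, cov=cov, eta=eta)),
                  t0, t1, epsabs=0.0, epsrel=epsrel, limit=400)
    return val


def gauss_hermite_marginal(loglik, omega2: float, nodes: int = 64) -> float:
    """log of int exp(loglik(eta)) * Normal(eta; 0, omega2) deta.

    Adaptive: the quadrature is centred and scaled at the mode of the joint
    log-density, located by bounded scalar minimisation.
    """
    def joint(e: float) -> float:
        return loglik(e) - 0.5 * e * e / omega2 - 0.5 * np.log(2 * np.pi * omega2)

    res = minimize_scalar(lambda e: -joint(e), bounds=(-20.0, 20.0),
                          method="bounded", options={"xatol": 1e-12})
    mode = float(res.x)
    h = 1e-5 * max(abs(mode), 1.0)
    d2 = (joint(mode + h) - 2.0 * joint(mode) + joint(mode - h)) / h**2
    sigma = 1.0 / np.sqrt(max(-d2, 1e-12))
    x, w = hermgauss(nodes)
    pts = mode + np.sqrt(2.0) * sigma * x
    vals = np.array([joint(p) for p in pts])
    return float(logsumexp(vals + x**2 + np.log(w)) + np.log(np.sqrt(2.0) * sigma))


def lifelines_km(durations, observed):
    """Reference product-limit estimate: (event_times, survival)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    times = np.unique(np.asarray(durations)[np.asarray(observed, dtype=bool)])
    return times, sf.loc[times, "KM_estimate"].to_numpy()


def make_history(subject_id: str, event_times, terminal: float,
                 covariates: dict[str, float] | None = None,
                 switches: dict[str, tuple[float, float, float]] | None = None,
                 ) -> SubjectHistory:
    """Build a SubjectHistory directly.

    ``covariates`` are static values; ``switches`` maps a name to
    (switch_time, value_before, value_after) for a one-step path.
    """
    covariates = covariates or {}
    switches = switches or {}
    path_times = np.array([0.0] + sorted(s[0] for s in switches.values()) + [terminal])
    path_times = np.unique(path_times)
    values = {}
    for k, v in covariates.items():
        values[k] = np.full(path_times.size, float(v))
    for k, (t_sw, before, after) in switches.items():
        values[k] = np.where(path_times < t_sw, float(before), float(after))
    return SubjectHistory(
        subject_id=subject_id,
        event_times=np.asarray(event_times, dtype=float),
        terminal_time=float(terminal),
        path_times=path_times,
        path_values=values,
    )
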