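"""Sampling-importance resampling (SIR) parameter uncertainty.

Parameter vectors are proposed from a multivariate normal centred at the
maximum-likelihood estimates on the estimation scale (log theta1, shape,
coefficients, log omega2) with the asymptotic covariance inflated by a
factor ``c`` (default 1.5).  Each proposal is weighted by

    w  ~  exp(-(OFV(psi) - OFV_min) / 2) / q(psi),

i.e. the likelihood against the proposal density (a flat prior on the
estimation scale is implicit, the pharmacometric convention), and ``m``
vectors are resampled with replacement proportionally to the weights.
Per-parameter relative standard errors (100 * SD / |point estimate|) and
percentile 95% intervals are reported on the natural scale.  If the
effective sample size degenerates the proposal is automatically re-inflated
and the weighting repeated (up to three retries).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, subject_histories
from .likelihood import Design, FitResult, _marginals_from_design

__all__ = ["SIRResult", "sir"]

log = logging.getLogger(__name__)


@dataclass
class SIRResult:
    """Resampled parameter vectors and the summaries derived from them."""

    param_names: list[str]
    point: np.ndarray              # natural-scale point estimates
    samples: np.ndarray            # (m, p) natural-scale resamples
    rse_pct: np.ndarray
    ci95: np.ndarray               # (p, 2) percentile bounds
    ess: float
    n_proposal: int
    m_resample: int
    inflation: float

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.param_names,
            "estimate": self.point,
            "rse_pct": self.rse_pct,
            "ci95_lo": self.ci95[:, 0],
            "ci95_hi": self.ci95[:, 1],
            "ess": self.ess,
        })


def _to_psi(nat: np.ndarray, names: Sequence[str]) -> np.ndarray:
    psi = np.array(nat, dtype=float)
    for i, n in enumerate(names):
        if n in ("theta1", "omega2"):
            psi[i] = np.log(nat[i])
    return psi


def _to_nat(psi: np.ndarray, names: Sequence[str]) -> np.ndarray:
    nat = np.array(psi, dtype=float)
    for i, n in enumerate(names):
        if n in ("theta1", "omega2"):
            nat[i] = np.exp(psi[i])
    return nat


def _psi_covariance(cov_nat: np.ndarray, nat: np.ndarray, names: Sequence[str]) -> np.ndarray:
    # delta method: d psi / d nat is diagonal (1/x on log-transformed axes)
    j = np.ones(len(names))
    for i, n in enumerate(names):
        if n in ("theta1", "omega2"):
            j[i] = 1.0 / nat[i]
    return cov_nat * np.outer(j, j)


def _sir_core(point_psi: np.ndarray, cov_psi: np.ndarray,
              ofv_psi: Callable[[np.ndarray], float], ofv_min: float,
              n_proposal: int, m_resample: int, inflation: float,
              rng: np.random.Generator, max_retries: int = 3):
    """Propose, weight and resample on the estimation scale."""
    p = point_psi.size
    for attempt in range(max_retries + 1):
        c = inflation * (2.0 ** attempt)
        chol = np.linalg.cholesky(c * cov_psi)
        z = rng.standard_normal((n_proposal, p))
        psi = point_psi + z @ chol.T
        # log proposal density (constants cancel in the normalised weights)
        log_q = -0.5 * np.sum(z**2, axis=1) - np.sum(np.log(np.diag(chol)))
        ofv = np.array([ofv_psi(v) for v in psi])
        log_w = -0.5 * (ofv - ofv_min) - log_q
        log_w -= log_w.max()
        w = np.exp(log_w)
        w /= w.sum()
        ess = float(1.0 / np.sum(w**2))
        if ess >= 0.01 * n_proposal or attempt == max_retries:
            if ess < 0.01 * n_proposal:
                warnings.warn(f"SIR weights remain degenerate (ESS={ess:.1f}) after retries")
            idx = rng.choice(n_proposal, size=m_resample, replace=True, p=w)
            return psi[idx], ess, c
        warnings.warn(f"SIR weights degenerate (ESS={ess:.1f}); inflating proposal")
    raise AssertionError("unreachable")


def sir(fit_result: FitResult, ds: Dataset, n_proposal: int = 5000,
        m_resample: int = 1000, inflation: float = 1.5,
        seed: int | None = None, rng: np.random.Generator | None = None) -> SIRResult:
    """SIR uncertainty for a converged fit with an available covariance."""
    if not fit_result.converged:
        raise ValueError("SIR requires a converged fit")
    if fit_result.covariance is None:
        raise ValueError("SIR requires the asymptotic covariance of the fit")
    if rng is None:
        rng = np.random.default_rng(seed)

    spec = fit_result.spec
    hists = subject_histories(ds)
    centers = {e.name: e.center for e in fit_result.model.effects}
    D = Design(hists, spec.covariates, centers)
    names = fit_result.param_names
    k = 1 + int(spec.has_shape)
    n_cov = len(spec.covariates)

    def ofv_psi(psi: np.ndarray) -> float:
        nat = _to_nat(psi, names)
        theta1 = float(nat[0])
        theta2 = float(nat[1]) if spec.has_shape else None
        beta = nat[k:k + n_cov]
        omega2 = float(nat[-1]) if spec.estimate_frailty else 0.0
        llm, _ = _marginals_from_design(spec.family, theta1, theta2, beta, omega2, D)
        return np.inf if llm is None else float(-2.0 * llm.sum())

    point = fit_result.estimates
    psi0 = _to_psi(point, names)
    cov_psi = _psi_covariance(fit_result.covariance, point, names)
    samples_psi, ess, used_inflation = _sir_core(
        psi0, cov_psi, ofv_psi, fit_result.ofv, n_proposal, m_resample, inflation, rng
    )
    samples = np.vstack([_to_nat(v, names) for v in samples_psi])
    sd = samples.std(axis=0, ddof=1)
    rse = 100.0 * sd / np.abs(point)
    ci = np.percentile(samples, [2.5, 97.5], axis=0).T
    return SIRResult(param_names=list(names), point=np.asarray(point, dtype=float),
                     samples=samples, rse_pct=rse, ci95=ci, ess=ess,
                     n_proposal=n_proposal, m_resample=m_resample,
                     inflation=used_inflation)
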