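"""Likelihood-ratio testing and stepwise covariate model building.

Nested models are compared by the drop in objective function value
(OFV = -2 log-likelihood), which is chi-square distributed under the null
with degrees of freedom equal to the number of added parameters.  Covariate
screening fits each candidate alone on top of the base model; the stepwise
procedure then adds greedily (largest significant OFV drop first, alpha =
0.05 per addition) and finally tries to remove each retained covariate,
dropping any whose removal raises the OFV by less than the alpha = 0.01
threshold (6.635 for one degree of freedom).  Exact chi-square quantiles are
used for every comparison; thresholds are only rounded for display, so
borderline decisions are never flipped by rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, subject_histories
from .likelihood import Design, FitResult, FitSpec, fit

__all__ = [
    "LRTResult",
    "SelectionStep",
    "SelectionTrace",
    "chi2_pvalue",
    "lrt_threshold",
    "likelihood_ratio_test",
    "univariate_screen",
    "stepwise",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRTResult:
    delta_ofv: float
    df: int
    p_value: float


def chi2_pvalue(delta_ofv: float, df: int = 1) -> float:
    """Upper-tail chi-square probability of an OFV reduction."""
    if delta_ofv < 0:
        raise ValueError("delta_ofv must be >= 0; order the models as reduced minus full")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(delta_ofv, df))


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """OFV reduction needed for significance at level alpha (chi-square quantile)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.isf(alpha, df))


def likelihood_ratio_test(ofv_reduced: float, ofv_full: float, df: int = 1) -> LRTResult:
    delta = ofv_reduced - ofv_full
    return LRTResult(delta_ofv=delta, df=df, p_value=chi2_pvalue(max(delta, 0.0), df))


@dataclass(frozen=True)
class SelectionStep:
    phase: str          # "forward" | "backward"
    step: int
    candidate: str
    action: str         # "add" | "reject" | "drop" | "keep" | "failed"
    delta_ofv: float    # OFV(model with candidate) - OFV(model without), < 0 is better
    p_value: float
    ofv: float          # OFV of the model after the decision
    covariates: tuple[str, ...]


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])

    @property
    def selected(self) -> tuple[str, ...]:
        return self.steps[-1].covariates if self.steps else ()


def _screen_row(name: str, res: FitResult, base_ofv: float) -> dict:
    delta = res.ofv - base_ofv
    p = chi2_pvalue(max(-delta, 0.0)) if delta < 0 else 1.0
    i = res.param_names.index(name)
    rse = float(res.rse_pct[i]) if res.rse_pct is not None else np.nan
    hr, lo, hi = res.ahr.get(name, (np.nan, np.nan, np.nan))
    return {"covariate": name, "delta_ofv": delta, "p_value": p, "rse_pct": rse,
            "hr": hr, "ci95_lo": lo, "ci95_hi": hi, "iiv_pct": res.iiv_pct,
            "converged": res.converged}


def univariate_screen(base_spec: FitSpec, ds: Dataset, candidates: Sequence[str],
                      base_fit: FitResult | None = None) -> pd.DataFrame:
    """One single-covariate fit per candidate against a common base model.

    Returns a table (one row per candidate, sorted by OFV drop) with the OFV
    change, likelihood-ratio p-value, coefficient RSE%, unadjusted hazard
    ratio with its 95% CI and the re-estimated frailty IIV%.  Individual fit
    failures are recorded in their row and do not stop the screen.
    """
    hists = subject_histories(ds)
    union = tuple(dict.fromkeys(tuple(base_spec.covariates) + tuple(candidates)))
    centers = _centers_for(base_spec, ds, union)
    design = Design(hists, union, centers)
    if base_fit is None:
        base_fit = fit(base_spec, ds, compute_covariance=False, _design=design)
    rows = []
    for name in candidates:
        spec_c = base_spec.with_covariates(tuple(base_spec.covariates) + (name,)) \
            if name not in base_spec.covariates else base_spec
        spec_c = replace(spec_c, centers=centers)
        try:
            res = fit(spec_c, ds, start=base_fit.model, _design=design)
            rows.append(_screen_row(name, res, base_fit.ofv))
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("screen fit failed for %s: %s", name, exc)
            rows.append({"covariate": name, "delta_ofv": np.nan, "p_value": np.nan,
                         "rse_pct": np.nan, "hr": np.nan, "ci95_lo": np.nan,
                         "ci95_hi": np.nan, "iiv_pct": np.nan, "converged": False})
    out = pd.DataFrame(rows).sort_values("delta_ofv", na_position="last")
    return out.reset_index(drop=True)


def _centers_for(spec: FitSpec, ds: Dataset, names: Sequence[str]) -> dict[str, float]:
    centers = dict(spec.centers or {})
    for c in names:
        if c not in centers:
            centers[c] = float(ds.medians[c]) if ds.schema.get(c) == "continuous" else 0.0
    return centers


def stepwise(base_spec: FitSpec, ds: Dataset, candidates: Sequence[str],
             forward_alpha: float = 0.05, backward_alpha: float = 0.01,
             ) -> tuple[FitSpec, SelectionTrace]:
    """Greedy forward addition then backward elimination by likelihood ratio.

    Forward: each round refits every remaining candidate on the current
    model and adds the one with the largest significant OFV drop
    (p < ``forward_alpha``); stops when none qualifies.  Backward: from the
    full model, each retained covariate is removed in turn and dropped if
    its removal raises the OFV by less than the ``backward_alpha`` threshold,
    iterating until the model is stable.
    """
    hists = subject_histories(ds)
    union = tuple(dict.fromkeys(tuple(base_spec.covariates) + tuple(candidates)))
    centers = _centers_for(base_spec, ds, union)
    design = Design(hists, union, centers)
    base_spec = replace(base_spec, centers=centers)

    warm: dict = {"model": None}

    def _fit(covs: tuple[str, ...]) -> FitResult:
        return fit(base_spec.with_covariates(covs), ds, start=warm["model"],
                   compute_covariance=False, _design=design)

    trace = SelectionTrace()
    current = tuple(base_spec.covariates)
    current_fit = _fit(current)
    current_ofv = current_fit.ofv
    warm["model"] = current_fit.model
    remaining = [c for c in candidates if c not in current]
    fwd_threshold = lrt_threshold(forward_alpha, 1)
    bwd_threshold = lrt_threshold(backward_alpha, 1)
    step = 0

    while remaining:
        results: dict[str, FitResult] = {}
        for cand in remaining:
            try:
                results[cand] = _fit(current + (cand,))
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("forward step failed for %s: %s", cand, exc)
                step += 1
                trace.steps.append(SelectionStep("forward", step, cand, "failed",
                                                 np.nan, np.nan, current_ofv, current))
        if not results:
            break
        best = min(results, key=lambda c: results[c].ofv)
        delta = results[best].ofv - current_ofv
        p = chi2_pvalue(max(-delta, 0.0)) if delta < 0 else 1.0
        step += 1
        if -delta >= fwd_threshold:
            current = current + (best,)
            current_ofv = results[best].ofv
            warm["model"] = results[best].model
            remaining.remove(best)
            trace.steps.append(SelectionStep("forward", step, best, "add",
                                             delta, p, current_ofv, current))
        else:
            trace.steps.append(SelectionStep("forward", step, best, "reject",
                                             delta, p, current_ofv, current))
            break

    added = [c for c in current if c not in base_spec.covariates]
    changed = True
    while changed and added:
        changed = False
        removal: dict[str, FitResult] = {}
        for cand in added:
            reduced = tuple(c for c in current if c != cand)
            try:
                removal[cand] = _fit(reduced)
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("backward step failed for %s: %s", cand, exc)
        if not removal:
            break
        weakest = min(removal, key=lambda c: removal[c].ofv)
        rise = removal[weakest].ofv - current_ofv  # >= 0: cost of removing it
        p = chi2_pvalue(max(rise, 0.0))
        step += 1
        if rise < bwd_threshold:
            current = tuple(c for c in current if c != weakest)
            current_ofv = removal[weakest].ofv
            warm["model"] = removal[weakest].model
            added.remove(weakest)
            trace.steps.append(SelectionStep("backward", step, weakest, "drop",
                                             rise, p, current_ofv, current))
            changed = True
        else:
            trace.steps.append(SelectionStep("backward", step, weakest, "keep",
                                             rise, p, current_ofv, current))
    final_spec = base_spec.with_covariates(current)
    return final_spec, trace
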