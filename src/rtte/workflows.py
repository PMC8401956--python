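"""End-to-end analysis workflows: base-model comparison and the full pipeline.

The full pipeline chains the stages of the analysis: generate or load a
dataset, compare the constant/Gompertz/Weibull base hazards by likelihood
ratio, screen candidate covariates univariately, build the covariate model
by forward addition (p < 0.05) and backward elimination (p < 0.01), fit the
final model, quantify uncertainty by SIR, and validate by Kaplan-Meier
visual predictive checks (overall and stratified on the six-month
cumulative dose at 50 g).  Every run directory contains a machine-readable
manifest with the configuration, seed and per-stage status, sufficient to
reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import COHORT_SCHEMA, CohortSpec, GeneratedCohort, generate, summarize
from .data import Dataset, read_dataset
from .likelihood import FitResult, FitSpec, fit
from .selection import chi2_pvalue, stepwise, univariate_screen
from .simulate import km_vpc, strata_by_threshold
from .sir import sir

__all__ = ["RunConfig", "run_base_models", "run_full_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_CANDIDATES = (
    "AGE", "AAP", "CTDD", "STATIN", "TAP", "SEX", "SMOK", "BMI", "DOSE",
    "ODD", "ANTICONV", "SSRI", "BZD", "TCA", "MALAY", "CHINESE", "INDIAN",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    seed: int = 12345
    dataset: str | None = None            # CSV path; when None, a cohort is generated
    schema: dict[str, str] | None = None  # covariate schema for an external CSV
    cohort_n: int = 116
    family: str = "weibull"
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    forward_alpha: float = 0.05
    backward_alpha: float = 0.01
    centers: dict[str, float] | None = None  # e.g. {"AGE": 41, "CTDD": 34}
    n_sim: int = 1000
    horizon: float = 800.0
    ctdd_cutoff: float = 50.0
    sir_proposal: int = 5000
    sir_resample: int = 1000
    outdir: str = "rtte_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "candidates" in raw:
            raw["candidates"] = tuple(raw["candidates"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["candidates"] = list(d["candidates"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _load_or_generate(cfg: RunConfig) -> tuple[Dataset, GeneratedCohort | None]:
    if cfg.dataset is not None:
        schema = cfg.schema or COHORT_SCHEMA
        return read_dataset(cfg.dataset, schema), None
    cohort = generate(CohortSpec(n_subjects=cfg.cohort_n), seed=cfg.seed)
    return cohort.dataset, cohort


def run_base_models(ds: Dataset, estimate_frailty: bool = True,
                    centers: dict[str, float] | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit the three base hazard families and compare them to the constant one.

    Returns a comparison table (parameter counts, OFV, OFV drop versus the
    constant hazard and its chi-square p-value) plus the fitted results; the
    lowest-OFV family is the natural base model.
    """
    fits: dict[str, FitResult] = {}
    rows = []
    for family in ("constant", "gompertz", "weibull"):
        spec = FitSpec(family=family, estimate_frailty=estimate_frailty, centers=centers)
        try:
            fits[family] = fit(spec, ds, compute_covariance=False)
        except Exception as exc:
            log.warning("base model %s failed: %s", family, exc)
            rows.append({"family": family, "n_parameters": np.nan, "ofv": np.nan,
                         "delta_ofv": np.nan, "p_value": np.nan, "converged": False})
            continue
    ofv0 = fits["constant"].ofv if "constant" in fits else np.nan
    for family, res in fits.items():
        delta = ofv0 - res.ofv
        df = 1 if family != "constant" else 1
        p = chi2_pvalue(max(delta, 0.0), df) if family != "constant" and np.isfinite(delta) else (
            1.0 if family == "constant" else np.nan)
        rows.append({"family": family, "n_parameters": len(res.param_names),
                     "ofv": res.ofv, "delta_ofv": delta if family != "constant" else 0.0,
                     "p_value": p if family != "constant" else 1.0,
                     "converged": res.converged})
    table = pd.DataFrame(rows)
    return table, fits


def run_full_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and write tables, VPC output, plots and a manifest.

    A stage failure aborts the downstream stages; partial outputs are kept
    and the manifest records per-stage status.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    manifest = {
        "package": "rtte", "version": __version__, "seed": cfg.seed,
        "config": {**dataclasses.asdict(cfg), "candidates": list(cfg.candidates)},
        "stages": status, "artifacts": [],
    }
    artifacts: list[str] = manifest["artifacts"]

    def _save(name: str, writer) -> None:
        writer(outdir / name)
        artifacts.append(name)

    def _manifest() -> None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        ds, cohort = _load_or_generate(cfg)
        if cohort is not None:
            cohort.write(outdir)
            artifacts.extend(["cohort.csv", "truth.json"])
            _save("cohort_summary.csv", lambda p: summarize(cohort).to_csv(p, index=False))
        status["data"] = "ok"
    except Exception as exc:
        status["data"] = f"failed: {exc}"
        _manifest()
        raise

    stage = "base_models"
    try:
        base_table, base_fits = run_base_models(ds, centers=cfg.centers)
        _save("base_models.csv", lambda p: base_table.to_csv(p, index=False))
        best_family = base_table.dropna(subset=["ofv"]).sort_values("ofv").iloc[0]["family"]
        if cfg.family and cfg.family != best_family:
            log.info("configured family %s (lowest OFV was %s)", cfg.family, best_family)
        family = cfg.family or best_family
        status[stage] = "ok"

        stage = "screen"
        base_spec = FitSpec(family=family, centers=cfg.centers)
        screen = univariate_screen(base_spec, ds, cfg.candidates)
        _save("univariate_screen.csv", lambda p: screen.to_csv(p, index=False))
        status[stage] = "ok"

        stage = "stepwise"
        significant = tuple(screen.loc[screen["p_value"] < cfg.forward_alpha, "covariate"])
        final_spec, trace = stepwise(base_spec, ds, significant,
                                     cfg.forward_alpha, cfg.backward_alpha)
        _save("stepwise_trace.csv", lambda p: trace.to_frame().to_csv(p, index=False))
        status[stage] = "ok"

        stage = "final_fit"
        final = fit(final_spec, ds)
        _save("final_model.csv", lambda p: final.summary_table().to_csv(p, index=False))
        _save("final_model.json", lambda p: p.write_text(json.dumps(final.to_dict(), indent=2)))
        status[stage] = "ok"

        stage = "sir"
        sir_res = sir(final, ds, n_proposal=cfg.sir_proposal,
                      m_resample=cfg.sir_resample, seed=cfg.seed + 1)
        _save("sir_summary.csv", lambda p: sir_res.summary_table().to_csv(p, index=False))
        status[stage] = "ok"

        stage = "vpc"
        vpc_all = km_vpc(final.model, ds, n_sim=cfg.n_sim, horizon=cfg.horizon,
                         seed=cfg.seed + 2)
        _save("vpc_overall.csv", lambda p: vpc_all.to_frame().to_csv(p, index=False))
        vpc_ctdd = km_vpc(final.model, ds, n_sim=cfg.n_sim, horizon=cfg.horizon,
                          strata=strata_by_threshold("CTDD", cfg.ctdd_cutoff),
                          seed=cfg.seed + 2)
        _save("vpc_ctdd_strata.csv", lambda p: vpc_ctdd.to_frame().to_csv(p, index=False))
        try:
            from .plots import plot_vpc

            _save("vpc_overall.png", lambda p: plot_vpc(vpc_all, p))
            _save("vpc_ctdd_strata.png", lambda p: plot_vpc(vpc_ctdd, p))
        except Exception as exc:  # plotting must never sink the run
            log.warning("VPC plots skipped: %s", exc)
        status[stage] = "ok"
    except Exception as exc:
        status[stage] = f"failed: {exc}"
        _manifest()
        raise
    _manifest()
    artifacts.append("manifest.json")
    _manifest()
    return outdir
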