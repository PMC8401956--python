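"""Synthetic clozapine cohort generator.

Generates cohorts with the marginal demographic/clinical structure of the
clinic population the model was built for (n = 116 treatment-resistant
schizophrenia-spectrum patients started on clozapine): age, sex, race,
smoking, BMI, daily dose, dosing frequency and concomitant-medication
frequencies are drawn independently from the reported marginals; follow-up
(censoring) times come from a scaled Beta on [8, 800] weeks with mean 306;
and the six-month cumulative clozapine dose (CTDD, grams) is derived
mechanistically from the daily dose with lognormal adherence noise
calibrated once so the cohort median is about 34 g.  Improvement events are
then simulated from a specified frailty hazard model, whose parameters are
stored as ground truth for recovery tests.

Covariates are static per subject; non-event follow-up rows are emitted at
12-week intervals to mimic clinic visits, which affects only the recorded
covariate-path resolution, not the likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CATEGORICAL, CONTINUOUS, Dataset, from_frame
from .hazard import (
    CovariateEffect,
    HazardModel,
    HazardParameters,
    base_cumulative_hazard,
    base_inverse_cumulative_hazard,
)
from .simulate import MAX_EVENTS

__all__ = [
    "COHORT_SCHEMA",
    "DEFAULT_MODEL",
    "CohortSpec",
    "GeneratedCohort",
    "generate",
    "summarize",
]

#: covariate dialect written by the generator
COHORT_SCHEMA: dict[str, str] = {
    "AGE": CONTINUOUS,       # years at clozapine start
    "SEX": CATEGORICAL,      # 1 = female
    "SMOK": CATEGORICAL,
    "BMI": CONTINUOUS,       # kg/m^2
    "MALAY": CATEGORICAL,
    "CHINESE": CATEGORICAL,
    "INDIAN": CATEGORICAL,
    "DOSE": CONTINUOUS,      # clozapine total daily dose, mg
    "ODD": CATEGORICAL,      # once-daily dosing
    "TAP": CATEGORICAL,      # concomitant typical antipsychotic
    "AAP": CATEGORICAL,      # concomitant second atypical antipsychotic
    "STATIN": CATEGORICAL,
    "ANTICONV": CATEGORICAL,
    "SSRI": CATEGORICAL,
    "BZD": CATEGORICAL,
    "TCA": CATEGORICAL,
    "CTDD": CONTINUOUS,      # cumulative clozapine dose at six months, g
}

#: final-model estimates used as the default generating hazard: Weibull scale
#: 0.0022/week, shape 0.853, log-linear effects for age (per year, centred at
#: 41), concomitant atypical antipsychotic and six-month cumulative dose (per
#: gram, centred at 34), frailty SD 1.01 (IIV 101%).
DEFAULT_MODEL = HazardModel(
    params=HazardParameters("weibull", 0.0022, 0.853),
    effects=(
        CovariateEffect("AGE", -0.0438, 41.0),
        CovariateEffect("AAP", 1.39, 0.0),
        CovariateEffect("CTDD", 0.0183, 34.0),
    ),
    omega2=1.01**2,
)

# six months of dosing expressed in days
_SIX_MONTHS_DAYS = 26 * 7
# lognormal adherence noise on the six-month cumulative dose; the log-median
# was calibrated once (root-finding on the generator itself) so the cohort
# CTDD median is ~34 g, then frozen here
ADHERENCE_LOG_MEDIAN = -0.3101
ADHERENCE_SIGMA = 0.35


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, covariate marginals, censoring and the generating model."""

    n_subjects: int = 116
    model: HazardModel = DEFAULT_MODEL
    # continuous marginals: (mean, sd, low, high) truncated normals
    age: tuple[float, float, float, float] = (41.4, 12.2, 9.2, 78.4)
    bmi: tuple[float, float, float, float] = (25.6, 5.9, 13.3, 46.1)
    daily_dose: tuple[float, float, float, float] = (254.2, 172.4, 6.25, 825.0)
    # Bernoulli marginals
    p_female: float = 0.560
    p_smoker: float = 0.086
    p_once_daily: float = 0.449
    p_typical_ap: float = 0.112
    p_atypical_ap: float = 0.181
    p_statin: float = 0.112
    p_anticonvulsant: float = 0.224
    p_ssri: float = 0.224
    p_benzodiazepine: float = 0.069
    p_tca: float = 0.069
    # race: Malay / Chinese / Indian
    p_race: tuple[float, float, float] = (0.215, 0.638, 0.147)
    # censoring: scaled Beta on [low, high] weeks with the given mean and SD
    censor_range: tuple[float, float] = (8.0, 800.0)
    censor_mean: float = 306.0
    censor_sd: float = 200.0
    visit_interval: float = 12.0
    max_events: int = 10 * MAX_EVENTS  # heavy frailty tails are legitimate here

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        probs = [self.p_female, self.p_smoker, self.p_once_daily, self.p_typical_ap,
                 self.p_atypical_ap, self.p_statin, self.p_anticonvulsant,
                 self.p_ssri, self.p_benzodiazepine, self.p_tca, *self.p_race]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("marginal probabilities must lie in [0, 1]")
        for name in ("age", "bmi", "daily_dose"):
            mean, sd, lo, hi = getattr(self, name)
            if not lo <= hi or sd <= 0:
                raise ValueError(f"bad truncation bounds for {name}")
            if hi < mean - 6 * sd or lo > mean + 6 * sd:
                raise ValueError(f"infeasible truncation for {name}: bounds exclude mean +/- 6 SD")


@dataclass
class GeneratedCohort:
    """A generated dataset plus its ground truth and quick summaries."""

    dataset: Dataset
    model: HazardModel
    eta: np.ndarray              # per-subject frailty deviates actually used
    n_events: np.ndarray         # per-subject simulated event counts
    censor_times: np.ndarray
    spec: CohortSpec
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return self.eta.size

    @property
    def improver_fraction(self) -> float:
        return float(np.mean(self.n_events >= 1))

    @property
    def total_events(self) -> int:
        return int(self.n_events.sum())

    def truth_dict(self) -> dict:
        p = self.model.params
        return {
            "synthetic": True,
            "seed": self.seed,
            "family": p.family,
            "theta1": p.theta1,
            "theta2": p.theta2,
            "omega2": self.model.omega2,
            "effects": {e.name: {"coef": e.coef, "center": e.center}
                        for e in self.model.effects},
            "eta": self.eta.tolist(),
            "n_events": self.n_events.tolist(),
        }

    def write(self, directory) -> None:
        """Write the CSV dataset plus a ground-truth JSON sidecar."""
        from .data import write_dataset

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_dataset(self.dataset, directory / "cohort.csv")
        (directory / "truth.json").write_text(json.dumps(self.truth_dict(), indent=2))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds are never deep in a tail here)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _censor_beta_params(spec: CohortSpec) -> tuple[float, float]:
    lo, hi = spec.censor_range
    width = hi - lo
    m = (spec.censor_mean - lo) / width
    v = (spec.censor_sd / width) ** 2
    nu = m * (1.0 - m) / v - 1.0
    if nu <= 0:
        raise ValueError("censoring SD too large for the given range")
    return m * nu, (1.0 - m) * nu


def generate(spec: CohortSpec = CohortSpec(), seed: int | None = None,
             rng: np.random.Generator | None = None) -> GeneratedCohort:
    """Draw covariates, censoring and model-simulated events for a cohort."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = spec.n_subjects
    cov = pd.DataFrame({
        "AGE": _truncated_normal(rng, *spec.age, n),
        "SEX": (rng.random(n) < spec.p_female).astype(float),
        "SMOK": (rng.random(n) < spec.p_smoker).astype(float),
        "BMI": _truncated_normal(rng, *spec.bmi, n),
        "DOSE": _truncated_normal(rng, *spec.daily_dose, n),
        "ODD": (rng.random(n) < spec.p_once_daily).astype(float),
        "TAP": (rng.random(n) < spec.p_typical_ap).astype(float),
        "AAP": (rng.random(n) < spec.p_atypical_ap).astype(float),
        "STATIN": (rng.random(n) < spec.p_statin).astype(float),
        "ANTICONV": (rng.random(n) < spec.p_anticonvulsant).astype(float),
        "SSRI": (rng.random(n) < spec.p_ssri).astype(float),
        "BZD": (rng.random(n) < spec.p_benzodiazepine).astype(float),
        "TCA": (rng.random(n) < spec.p_tca).astype(float),
    })
    race = rng.choice(3, size=n, p=np.asarray(spec.p_race) / np.sum(spec.p_race))
    cov["MALAY"] = (race == 0).astype(float)
    cov["CHINESE"] = (race == 1).astype(float)
    cov["INDIAN"] = (race == 2).astype(float)
    adherence = np.minimum(
        np.exp(rng.normal(ADHERENCE_LOG_MEDIAN, ADHERENCE_SIGMA, size=n)), 1.0
    )
    cov["CTDD"] = cov["DOSE"] * _SIX_MONTHS_DAYS * adherence / 1000.0
    cov = cov[list(COHORT_SCHEMA)]

    a, b = _censor_beta_params(spec)
    lo, hi = spec.censor_range
    censor = lo + (hi - lo) * rng.beta(a, b, size=n)

    # events: covariates are static, so the order-statistics construction
    # vectorises across all subjects at once
    model = spec.model
    p = model.params
    lp = np.zeros(n)
    for eff in model.effects:
        lp += eff.coef * (cov[eff.name].to_numpy() - eff.center)
    eta = rng.normal(0.0, np.sqrt(model.omega2), size=n) if model.omega2 > 0 else np.zeros(n)
    lam = base_cumulative_hazard(p.family, p.theta1, p.theta2, 0.0, censor) * np.exp(lp + eta)
    n_events = rng.poisson(lam)
    if n_events.max(initial=0) > spec.max_events:
        raise RuntimeError(
            f"a subject drew {n_events.max()} events (> {spec.max_events}); "
            "check the generating parameters"
        )
    total = int(n_events.sum())
    sub_of_event = np.repeat(np.arange(n), n_events)
    u = rng.random(total) * lam[sub_of_event] / np.exp(lp + eta)[sub_of_event]
    ev_times = base_inverse_cumulative_hazard(p.family, p.theta1, p.theta2, 0.0, u)
    ev_times = np.minimum(ev_times, censor[sub_of_event])
    order = np.lexsort((ev_times, sub_of_event))
    sub_of_event, ev_times = sub_of_event[order], ev_times[order]

    # assemble rows: baseline visit, 12-weekly visits, events, terminal censor
    ids, times, dvs = [], [], []
    ev_split = np.split(ev_times, np.cumsum(n_events)[:-1])
    for i in range(n):
        visits = np.arange(0.0, censor[i], spec.visit_interval)
        t = np.concatenate([visits, ev_split[i], [censor[i]]])
        d = np.concatenate([
            np.zeros(visits.size, dtype=int),
            np.ones(ev_split[i].size, dtype=int),
            [0],
        ])
        order_i = np.lexsort((-d, t))
        # force the censor record last even if an event ties with it
        term = np.nonzero((t[order_i] == censor[i]) & (d[order_i] == 0))[0][-1]
        order_i = np.concatenate([np.delete(order_i, term), [order_i[term]]])
        ids.extend([f"S{i + 1:04d}"] * t.size)
        times.append(t[order_i])
        dvs.append(d[order_i])
    frame = pd.DataFrame({"ID": ids, "TIME": np.concatenate(times),
                          "DV": np.concatenate(dvs)})
    rep = np.repeat(np.arange(n), [v.size for v in times])
    for name in COHORT_SCHEMA:
        frame[name] = cov[name].to_numpy()[rep]

    dataset = from_frame(frame, COHORT_SCHEMA)
    return GeneratedCohort(dataset=dataset, model=model, eta=eta,
                           n_events=np.asarray(n_events), censor_times=censor,
                           spec=spec, seed=seed)


def summarize(cohort: GeneratedCohort) -> pd.DataFrame:
    """Cohort summary: mean +/- SD for continuous fields, n (%) for flags,
    plus event and censoring summaries."""
    ds = cohort.dataset
    base = ds.frame.groupby("ID", sort=False).head(1)
    n = len(base)
    rows = []
    for name, kind in ds.schema.items():
        col = base[name]
        if kind == CONTINUOUS:
            rows.append({"field": name, "kind": "continuous",
                         "mean": float(col.mean()), "sd": float(col.std(ddof=1)) if n > 1 else 0.0,
                         "n": np.nan, "pct": np.nan})
        else:
            k = int(col.sum())
            rows.append({"field": name, "kind": "categorical", "mean": np.nan,
                         "sd": np.nan, "n": k, "pct": 100.0 * k / n})
    improvers = int(np.sum(cohort.n_events >= 1))
    rows.append({"field": "improvers", "kind": "categorical", "mean": np.nan,
                 "sd": np.nan, "n": improvers, "pct": 100.0 * improvers / n})
    rows.append({"field": "events_total", "kind": "count", "mean": float(cohort.total_events),
                 "sd": np.nan, "n": cohort.total_events, "pct": np.nan})
    rows.append({"field": "censor_weeks", "kind": "continuous",
                 "mean": float(cohort.censor_times.mean()),
                 "sd": float(cohort.censor_times.std(ddof=1)) if n > 1 else 0.0,
                 "n": np.nan, "pct": np.nan})
    return pd.DataFrame(rows)
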