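"""Shared fixtures: a seeded mid-size synthetic cohort and its final-model fit."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rtte
from rtte.likelihood import FitSpec, fit

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort116() -> rtte.GeneratedCohort:
    """Default-condition synthetic cohort (n = 116, final-model parameters)."""
    return rtte.generate(rtte.CohortSpec(), seed=20260930)


@pytest.fixture(scope="session")
def fit116(cohort116) -> "rtte.FitResult":
    """Weibull frailty fit with the three final-model covariates."""
    spec = FitSpec(family="weibull", covariates=("AGE", "AAP", "CTDD"))
    res = fit(spec, cohort116.dataset)
    assert res.converged
    return res


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
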