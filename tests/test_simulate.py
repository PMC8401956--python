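"""Event simulation, Kaplan-Meier estimation and the KM visual predictive check."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from rtte.cohort import CohortSpec, generate
from rtte.data import subject_histories
from rtte.hazard import CovariateEffect, HazardModel, HazardParameters
from rtte.simulate import (
    first_event_times,
    kaplan_meier,
    km_evaluate,
    km_vpc,
    simulate_subject,
    strata_by_threshold,
)
from oracles import lifelines_km, make_history


def _model(family="constant", th1=0.1, th2=None, effects=(), omega2=0.0):
    return HazardModel(HazardParameters(family, th1, th2), tuple(effects), omega2)


class TestSimulateSubject:
    def test_vanishing_scale_gives_no_events(self, rng):
        m = _model(th1=1e-12)
        h = simulate_subject(m, make_history("a", [], 800.0), rng)
        assert h.n_events == 0

    def test_constant_hazard_mean_event_count(self, rng):
        lam, T, n = 0.1, 100.0, 10_000
        template = make_history("a", [], T)
        m = _model(th1=lam)
        counts = np.array([simulate_subject(m, template, rng).n_events for _ in range(n)])
        mc_se = np.sqrt(lam * T / n)
        assert abs(counts.mean() - lam * T) < 3 * mc_se

    @pytest.mark.parametrize(
        "family,th1,th2",
        [("constant", 0.08, None), ("gompertz", 0.01, 0.005), ("weibull", 0.005, 0.6)],
    )
    def test_events_strictly_increasing_within_horizon(self, rng, family, th1, th2):
        m = _model(family, th1, th2, effects=[CovariateEffect("X", 0.9)], omega2=0.3)
        template = make_history("a", [], 300.0, switches={"X": (40.0, 0.0, 1.0)})
        for _ in range(50):
            h = simulate_subject(m, template, rng)
            assert np.all(np.diff(h.event_times) > 0)
            assert np.all(h.event_times <= h.terminal_time)

    def test_runaway_event_guard(self, rng):
        m = _model(th1=5.0)
        with pytest.raises(RuntimeError):
            simulate_subject(m, make_history("a", [], 800.0), rng, max_events=100)

    def test_sampler_distribution_constant_hazard(self, rng):
        """KS distance of looped first-event draws against the exponential law."""
        lam = 0.1
        m = _model(th1=lam)
        template = make_history("a", [], 1000.0)
        first = []
        while len(first) < 20_000:
            h = simulate_subject(m, template, rng)
            if h.n_events:
                first.append(h.event_times[0])
        d = stats.kstest(first, "expon", args=(0, 1 / lam)).statistic
        assert d < 0.01


class TestFirstEventTimes:
    def test_vectorised_sampler_matches_exponential(self, rng):
        lam, n = 0.1, 100_000
        m = _model(th1=lam)
        hists = [make_history(f"s{i}", [], 1000.0) for i in range(200)]
        durs = []
        for _ in range(n // 200):
            d, obs = first_event_times(m, hists, rng)
            durs.extend(d[obs])
        d = stats.kstest(durs, "expon", args=(0, 1 / lam)).statistic
        assert d < 0.01

    def test_weibull_median_first_event(self, rng):
        th1, th2 = 0.0022, 0.853
        m = _model("weibull", th1, th2)
        # analytic median of the first-event law: H0(t) = log 2
        t_med = (np.log(2.0) * (th2 + 1) / th1) ** (1.0 / (th2 + 1))
        hists = [make_history(f"s{i}", [], 10 * t_med) for i in range(500)]
        below = []
        for _ in range(40):
            d, obs = first_event_times(m, hists, rng)
            below.extend((d[obs] <= t_med).tolist())
        assert abs(np.mean(below) - 0.5) < 0.015

    def test_piecewise_covariate_path_first_event_law(self, rng):
        """Segmental inversion: empirical first-event CDF matches the
        piecewise-exponential survival with a covariate switch."""
        lam, coef, t_sw, T = 0.02, 1.5, 30.0, 400.0
        m = _model(th1=lam, effects=[CovariateEffect("X", coef)])
        hists = [make_history(f"s{i}", [], T, switches={"X": (t_sw, 0.0, 1.0)})
                 for i in range(5000)]
        d, obs = first_event_times(m, hists, rng)

        def surv(t):
            h2 = lam * np.exp(coef)
            return np.where(t < t_sw, np.exp(-lam * t),
                            np.exp(-lam * t_sw - h2 * (t - t_sw)))

        for t in (10.0, 30.0, 60.0, 120.0):
            emp = np.mean(d > t)  # censoring at T=400 is negligible here
            assert emp == pytest.approx(float(surv(np.array(t))), abs=0.02)


class TestKaplanMeier:
    def test_two_subject_toy(self):
        hists = [make_history("a", [1.0], 1.0), make_history("b", [2.0], 2.0)]
        km = kaplan_meier(hists)
        assert km.times.tolist() == [1.0, 2.0]
        assert km.survival.tolist() == [0.5, 0.0]

    def test_all_censored(self):
        hists = [make_history(s, [], 50.0 + i) for i, s in enumerate("abc")]
        km = kaplan_meier(hists)
        assert km.times.size == 0
        assert km.censor_times.size == 3
        np.testing.assert_array_equal(km_evaluate(km, np.array([0.0, 100.0])), 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([])

    def test_matches_reference_product_limit(self, rng):
        durations = rng.integers(1, 30, size=60).astype(float)
        observed = rng.random(60) < 0.6
        hists = [
            make_history(f"s{i}", [t] if o else [], t if o else t)
            for i, (t, o) in enumerate(zip(durations, observed))
        ]
        km = kaplan_meier(hists)
        ref_times, ref_surv = lifelines_km(durations, observed)
        np.testing.assert_array_equal(km.times, ref_times)
        np.testing.assert_allclose(km.survival, ref_surv, rtol=1e-12)

    def test_second_event_curve_is_below_first(self, cohort116):
        hists = subject_histories(cohort116.dataset)
        k1 = kaplan_meier(hists, event_number=1)
        k2 = kaplan_meier(hists, event_number=2)
        grid = np.arange(0.0, 301.0)
        assert np.all(km_evaluate(k2, grid) >= km_evaluate(k1, grid) - 1e-12)

    def test_km_evaluate_step_semantics(self):
        hists = [make_history("a", [10.0], 10.0), make_history("b", [], 20.0)]
        km = kaplan_meier(hists)
        np.testing.assert_allclose(
            km_evaluate(km, np.array([9.9, 10.0, 15.0])), [1.0, 0.5, 0.5]
        )


class TestKMVPC:
    def test_single_simulation_band_collapses(self, cohort116, fit116):
        v = km_vpc(fit116.model, cohort116.dataset, n_sim=1, horizon=400.0, seed=0)
        b = v.band()
        np.testing.assert_array_equal(b.pi_lo, b.pi_hi)
        np.testing.assert_array_equal(b.pi_lo, b.pi_med)

    def test_deterministic_under_seed(self, cohort116, fit116):
        v1 = km_vpc(fit116.model, cohort116.dataset, n_sim=20, horizon=300.0, seed=9)
        v2 = km_vpc(fit116.model, cohort116.dataset, n_sim=20, horizon=300.0, seed=9)
        np.testing.assert_array_equal(v1.band().pi_lo, v2.band().pi_lo)
        np.testing.assert_array_equal(v1.band().observed, v2.band().observed)

    def test_band_orders_and_starts_at_one(self, cohort116, fit116):
        v = km_vpc(fit116.model, cohort116.dataset, n_sim=50, horizon=400.0, seed=4)
        b = v.band()
        assert np.all(b.pi_lo <= b.pi_med + 1e-12)
        assert np.all(b.pi_med <= b.pi_hi + 1e-12)
        assert b.pi_med[0] == 1.0 and b.observed[0] == 1.0

    def test_self_consistency_coverage(self):
        """Observed data generated by the model fall inside their own band."""
        cov = []
        for seed in (31, 32):
            cohort = generate(CohortSpec(n_subjects=116), seed=seed)
            v = km_vpc(cohort.model, cohort.dataset, n_sim=100, seed=seed)
            cov.append(v.band().coverage(upto=float(cohort.censor_times.max())))
        assert np.mean(cov) > 0.85

    def test_high_cumulative_dose_stratum_improves_earlier(self, cohort116, fit116):
        v = km_vpc(fit116.model, cohort116.dataset, n_sim=60, horizon=300.0,
                   strata=strata_by_threshold("CTDD", 50.0), seed=2)
        low = v.band("CTDD<50")
        high = v.band("CTDD>=50")
        assert high.pi_med.mean() < low.pi_med.mean()
        frame = v.to_frame()
        assert set(frame["stratum"]) == {"CTDD<50", "CTDD>=50"}
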