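"""Subject likelihood, Laplace marginal, OFV and maximum-likelihood fitting."""

from __future__ import annotations

import numpy as np
import pytest

from rtte.cohort import CohortSpec, generate
from rtte.hazard import CovariateEffect, HazardModel, HazardParameters
from rtte.likelihood import (
    FitSpec,
    fit,
    laplace_marginal,
    subject_loglik,
    total_ofv,
)
from oracles import gauss_hermite_marginal, make_history, quad_cumhaz


def _const(lam, omega2=0.0, effects=()):
    return HazardModel(HazardParameters("constant", lam), tuple(effects), omega2)


def _weib(th1, th2, omega2=0.0, effects=()):
    return HazardModel(HazardParameters("weibull", th1, th2), tuple(effects), omega2)


class TestSubjectLoglik:
    def test_no_event_constant_hazard(self):
        h = make_history("a", [], 2.0)
        assert subject_loglik(_const(0.5), h) == pytest.approx(-1.0)

    def test_one_event_constant_hazard(self):
        h = make_history("a", [1.0], 2.0)
        assert subject_loglik(_const(0.5), h) == pytest.approx(np.log(0.5) - 1.0)

    def test_weibull_two_events_vs_quadrature(self):
        m = _weib(0.0022, 0.853)
        h = make_history("a", [30.0, 200.0], 500.0)
        expect = (np.log(0.0022 * 30.0**0.853) + np.log(0.0022 * 200.0**0.853)
                  - quad_cumhaz(m, 0.0, 500.0))
        assert subject_loglik(m, h) == pytest.approx(expect, rel=1e-9)

    def test_piecewise_covariate_splits_the_integral(self):
        eff = CovariateEffect("AAP", 1.2)
        m = _const(0.05, effects=[eff])
        h = make_history("a", [40.0], 100.0, switches={"AAP": (20.0, 0.0, 1.0)})
        # event at 40 happens on the AAP=1 segment
        expect = (np.log(0.05 * np.exp(1.2))
                  - 0.05 * 20.0 - 0.05 * np.exp(1.2) * 80.0)
        assert subject_loglik(m, h) == pytest.approx(expect, rel=1e-12)

    def test_frailty_shifts_by_count_and_scales_integral(self):
        m = _const(0.1)
        h = make_history("a", [5.0, 9.0], 20.0)
        l0 = subject_loglik(m, h, eta=0.0)
        l1 = subject_loglik(m, h, eta=0.7)
        expect = l0 + 2 * 0.7 - 0.1 * 20.0 * (np.exp(0.7) - 1.0)
        assert l1 == pytest.approx(expect, rel=1e-10)


class TestLaplaceMarginal:
    def test_degenerate_frailty_equals_conditional(self):
        m = _weib(0.0022, 0.853, omega2=0.0)
        h = make_history("a", [30.0, 100.0], 400.0)
        assert laplace_marginal(m, h) == pytest.approx(subject_loglik(m, h, 0.0), rel=1e-12)

    def test_one_event_constant_against_exact_marginal(self):
        """The frozen exact value of this integral is -5.898669185188203
        (adaptive quadrature); the Laplace value sits 2.8e-3 above it, the
        characteristic skewness error of the approximation at one event."""
        m = _const(0.05, omega2=0.5)
        h = make_history("a", [10.0], 60.0)
        exact = -5.898669185188203
        gh = gauss_hermite_marginal(lambda e: subject_loglik(m, h, e), 0.5)
        assert gh == pytest.approx(exact, abs=1e-9)
        assert laplace_marginal(m, h) == pytest.approx(exact, abs=5e-3)

    def test_randomised_toy_subjects_error_envelope(self, rng):
        """Laplace vs adaptive 64-node Gauss-Hermite on <=5-event subjects.

        With so few events per subject and frailty variances up to 2 the
        Laplace approximation carries an irreducible skewness error of order
        1e-2 in the per-subject log-marginal; the envelope asserted here was
        mapped against exact quadrature.
        """
        worst = 0.0
        for _ in range(30):
            fam = rng.choice(["constant", "weibull"])
            omega2 = float(rng.uniform(0.05, 2.0))
            T = float(rng.uniform(20.0, 400.0))
            n_ev = int(rng.integers(0, 6))
            ev = np.sort(rng.uniform(0.5, T, size=n_ev))
            if fam == "constant":
                m = _const(float(rng.uniform(0.002, 0.05)), omega2=omega2)
            else:
                m = _weib(float(rng.uniform(0.001, 0.02)),
                          float(rng.uniform(-0.3, 1.2)), omega2=omega2)
            h = make_history("a", ev, T)
            gh = gauss_hermite_marginal(lambda e: subject_loglik(m, h, e), omega2)
            worst = max(worst, abs(laplace_marginal(m, h) - gh))
        assert worst < 0.03

    def test_laplace_error_vanishes_with_event_count(self, rng):
        """The approximation is first-order accurate in 1/n_events."""
        omega2 = 1.0
        T = 300.0
        errs = {}
        for n_ev in (2, 100):
            ev = np.sort(rng.uniform(1.0, T, size=n_ev))
            m = _const(n_ev / T, omega2=omega2)
            h = make_history("a", ev, T)
            gh = gauss_hermite_marginal(lambda e: subject_loglik(m, h, e), omega2)
            errs[n_ev] = abs(laplace_marginal(m, h) - gh)
        assert errs[100] < errs[2]
        assert errs[100] < 1e-3

    def test_no_event_marginal_is_a_log_probability(self):
        m = _const(0.02, omega2=1.0)
        h = make_history("a", [], 150.0)
        assert laplace_marginal(m, h) <= 0.0


class TestTotalOFV:
    def test_single_subject_matches_conditional(self):
        m = _const(0.5)
        h = make_history("a", [1.0], 2.0)
        assert total_ofv(m, [h]) == pytest.approx(-2.0 * subject_loglik(m, h))

    def test_additive_over_duplicated_subjects(self):
        m = _weib(0.003, 0.8, omega2=0.8)
        hs = [make_history(f"s{i}", [10.0 * (i + 1)], 300.0) for i in range(5)]
        assert total_ofv(m, hs + hs) == pytest.approx(2.0 * total_ofv(m, hs), rel=1e-12)

    def test_invariant_to_subject_order(self):
        m = _weib(0.003, 0.8, omega2=0.8)
        hs = [make_history(f"s{i}", [5.0 + 7 * i], 100.0 + 30 * i) for i in range(6)]
        assert total_ofv(m, hs) == pytest.approx(total_ofv(m, hs[::-1]), rel=1e-14)

    def test_constant_hazard_time_rescaling_shifts_ofv_analytically(self):
        # t -> c t with lambda -> lambda / c changes each event density by 1/c
        lam, c = 0.05, 3.0
        hs = [make_history("a", [4.0, 11.0], 50.0), make_history("b", [], 30.0)]
        hs_scaled = [make_history(h.subject_id, h.event_times * c, h.terminal_time * c)
                     for h in hs]
        n_events = sum(h.n_events for h in hs)
        ofv = total_ofv(_const(lam), hs)
        ofv_scaled = total_ofv(_const(lam / c), hs_scaled)
        assert ofv_scaled == pytest.approx(ofv + 2.0 * n_events * np.log(c), rel=1e-12)

    def test_true_parameters_beat_perturbed_at_large_n(self):
        cohort = generate(CohortSpec(n_subjects=500), seed=11)
        true = cohort.model
        perturbed = HazardModel(
            HazardParameters("weibull", true.params.theta1 * 2.0, true.params.theta2),
            true.effects, true.omega2,
        )
        assert total_ofv(true, cohort.dataset) < total_ofv(perturbed, cohort.dataset)


class TestFit:
    def test_constant_hazard_recovery_without_frailty(self, rng):
        lam, T, n = 0.05, 40.0, 200
        counts = rng.poisson(lam * T, size=n)
        hists = [make_history(f"s{i}", np.sort(rng.uniform(0, T, size=k)), T)
                 for i, k in enumerate(counts)]
        spec = FitSpec(family="constant", estimate_frailty=False)
        res = fit(spec, hists)
        assert res.converged
        lam_hat = res.model.params.theta1
        mc_se = np.sqrt(lam / (n * T))
        assert abs(lam_hat - lam) < 3 * mc_se
        # analytic Poisson SE: lambda_hat / sqrt(total events)
        se_expected = lam_hat / np.sqrt(counts.sum())
        assert res.se[0] == pytest.approx(se_expected, rel=0.05)

    def test_two_starts_agree(self):
        cohort = generate(CohortSpec(n_subjects=80), seed=3)
        spec = FitSpec(family="weibull", covariates=("AGE",))
        r1 = fit(spec, cohort.dataset, compute_covariance=False)
        start = HazardModel(HazardParameters("weibull", 0.01, 0.2),
                            (CovariateEffect("AGE", 0.0, 41.0),), 0.5)
        r2 = fit(spec, cohort.dataset, start=start, compute_covariance=False)
        assert abs(r1.ofv - r2.ofv) < 0.01

    def test_reported_transforms_are_consistent(self, fit116):
        res = fit116
        i = res.param_names.index("AAP")
        hr, lo, hi = res.ahr["AAP"]
        assert hr == pytest.approx(np.exp(res.estimates[i]), rel=1e-12)
        assert lo == pytest.approx(np.exp(res.estimates[i] - 1.96 * res.se[i]), rel=1e-12)
        assert hi == pytest.approx(np.exp(res.estimates[i] + 1.96 * res.se[i]), rel=1e-12)
        assert res.iiv_pct == pytest.approx(100 * np.sqrt(res.model.omega2), rel=1e-12)
        # RSE definition: 100 * SE / |estimate|
        np.testing.assert_allclose(res.rse_pct, 100 * res.se / np.abs(res.estimates))
        table = res.summary_table()
        assert list(table["parameter"]) == res.param_names + ["iiv_pct"]

    def test_eta_modes_shrink_with_event_count(self, fit116, cohort116):
        # subjects with many events should carry positive frailty modes
        many = cohort116.n_events > np.quantile(cohort116.n_events, 0.9)
        few = cohort116.n_events < np.quantile(cohort116.n_events, 0.1)
        assert fit116.eta_modes[many].mean() > fit116.eta_modes[few].mean()
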