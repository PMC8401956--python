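# Methods

This note records the statistical model, the numerical choices and the
known limitations of the package, at the level of detail a maintainer or
reviewer needs to judge what the tests do and do not establish.

## Model

Improvement events for subject *i* follow a nonhomogeneous Poisson process
on **total time** — weeks since the first clozapine dose — with intensity

h_i(t) = h0(t; θ1, θ2) · exp(η_i) · exp(Σ_k θ_k (x_ik(t) − c_k)),

where h0 is constant (θ1), Gompertz (θ1·e^{θ2 t}) or Weibull (θ1·t^{θ2}),
η_i ~ N(0, ω²) is a subject-level frailty on the scale parameter, and
covariates act log-linearly with continuous covariates centred at c_k
(cohort medians by default; 41 years for age and 34 g for the six-month
cumulative dose when reproducing the published parameterisation).  The
survival function S(t) = exp(−∫₀ᵗ h du) is the probability of no
improvement in (0, t].

Two modelling commitments deserve emphasis, because the clinical process
is more complicated than the model:

* **Total-time clock.** The hazard is a function of time since treatment
  start and does not reset at an event.  All three families define h(t)
  this way, and repeated improvements reuse the same h(t).
* **Continuously at risk.** Deterioration episodes are not represented as
  a state; a subject is treated as at risk of (another) improvement at
  every time until censoring.  Only improvement times and the final
  censoring time enter the likelihood.

Conditional on η, a subject's log-likelihood is the counting-process form
Σ_j log h(t_j) − ∫₀ᵀ h(u) du, with the integral split at covariate change
points (closed forms exist for all three families, tested against adaptive
quadrature at relative tolerance 1e-6).  Because the frailty is
multiplicative this collapses to A + n·η − B·e^η with per-subject
sufficient statistics (event count, Σ log t_j or Σ t_j, summed covariate
vectors, per-segment cumulative hazards), which makes each objective
evaluation O(#records) regardless of event counts.

## Laplace marginal likelihood and its accuracy

The frailty is integrated out per subject by the Laplace approximation:
the mode of f(η) = A + nη − B e^η − η²/(2ω²) is found (f is strictly
concave, so the mode is the unique root of a monotone function; the
implementation uses a vectorised safeguarded bisection to ~1e-12, which is
deterministic and immune to Newton overshoot — the Laplace value is
second-order insensitive to mode error), and the marginal is
f(η̂) + ½log 2π − ½log(B e^{η̂} + 1/ω²).  With ω² = 0 the marginal equals
the conditional at η = 0 exactly.

The OFV is −2·Σ marginals **including the 2π constants**; they cancel in
every ΔOFV, so likelihood-ratio comparisons match software that drops
them, while absolute OFVs differ by a data-independent constant.

Accuracy, mapped against exact quadrature (a 64-node adaptive
Gauss–Hermite oracle that itself agrees with brute-force quadrature to
1e-14): for subjects with 0–5 events and ω² up to 2 the Laplace
log-marginal carries a skewness error of median ≈5e-3 and maximum ≈2e-2;
the error contracts roughly as 1/n_events and is below 1e-3 by ~100 events
per subject.  This is an intrinsic property of the approximation, not of
the implementation, and it is inherited by everything downstream (OFVs,
LRT decisions at the margin).  Users needing exact marginals at very low
event counts should treat near-threshold ΔOFV values (within ~0.1 of a
cut-off) with caution.

## Estimation, uncertainty and selection

* Outer maximisation works on transformed parameters (log θ1, θ2 raw,
  coefficients raw, log ω²): a Nelder–Mead sweep (adaptive simplex,
  f-tolerance 1e-8) followed by a BFGS polish (gradient tolerance 1e-5).
  Refits from different starting points agree in OFV to <0.01 (tested).
* The covariance is the inverse central-difference Hessian of ½·OFV in the
  *natural* parameters (relative step 1e-3); RSE% = 100·SE/|estimate|;
  95% CIs are the normal approximation estimate ± 1.96·SE, which for
  positive parameters equals estimate·(1 ± 1.96·RSE/100).  aHR = exp(θ_k)
  with exp-transformed bounds.  IIV% is reported as 100·√ω² (the
  alternative CV formula 100·√(e^{ω²}−1) is deliberately not the default).
* Likelihood-ratio testing uses exact χ² quantiles everywhere (3.8415,
  5.9915, 6.6349); printed thresholds are rounded for display only, so
  borderline decisions never depend on rounding.
* Stepwise selection is greedy: each forward round refits every remaining
  candidate and adds the largest significant OFV drop (α = 0.05); backward
  elimination repeatedly removes the covariate whose removal costs least,
  while that cost is below the α = 0.01 threshold.  ω² is re-estimated in
  every fit, including the univariate screen.
* SIR draws n_proposal = 5000 vectors from N(ψ̂, 1.5·Ĉ) on the estimation
  scale (a flat prior on that scale is implicit — the pharmacometric
  convention), weights by likelihood/proposal, and resamples m = 1000 with
  replacement; degenerate weights (ESS < 1% of proposals) trigger
  automatic re-inflation (×2, up to three times).  RSE% uses
  SD(resamples)/|point estimate|.

## Simulation and the KM-VPC

Recurrent events are simulated by the order-statistics construction: with
total cumulative hazard Λ over the follow-up window, draw N ~ Poisson(Λ)
and invert N sorted uniforms through the piecewise closed-form cumulative
hazard.  This is exact for the process and fully vectorises when
covariates are static.  A guard (default 10⁴ events/subject, raised to
10⁵ in the generator and VPC where heavy frailty tails are legitimate)
catches pathological parameters.

The VPC reduces every dataset — observed and simulated — to time to
**first** improvement per subject (the standard single-curve display for
recurrent-event data; curves for the k-th event are available), computes
the product-limit estimator (cross-checked against lifelines exactly), and
overlays the observed curve on pointwise 2.5/50/97.5 percentile bands of
n_sim = 1000 replicates evaluated on a weekly grid to 800 weeks.
Replicates preserve each subject's covariates and censoring time; no
censoring process is simulated.  Replicate random streams are spawned per
replicate from a single seed, so results are reproducible and independent
of stratification.  Note that per-seed band coverage is highly correlated
across grid points (the late-time plateau of the KM curve is one random
quantity spanning hundreds of weekly points), so the ~95% pointwise
calibration emerges only as an average over many datasets — the acceptance
check averages 20 seeds.

## Synthetic cohort generator

The generator emulates the published cohort's *marginal* structure:
truncated-normal age (41.4 ± 12.2, range 9.2–78.4 y), BMI and daily dose
(254.2 ± 172.4, range 6.25–825 mg); Bernoulli flags at the reported
frequencies (56.0% female, 8.6% smokers, 18.1% concomitant atypical
antipsychotic, …); race as a three-level categorical (21.5/63.8/14.7%).
Follow-up is a Beta on [8, 800] weeks scaled to mean 306 with SD ≈ 200
(the source reports only mean and range; the SD is a documented synthetic
choice).  CTDD (g) is derived mechanistically as daily dose × 182 days,
times a lognormal adherence factor (σ = 0.35, capped at 1) whose
log-median (−0.3101) was calibrated once by root-finding so the cohort
CTDD median is ≈34 g, then frozen.  Covariates are otherwise drawn
independently — only marginals are published, so no copula is attempted —
and are static over time; non-event visit rows every 12 weeks mimic clinic
records and only affect covariate-path resolution.  Event histories are
then simulated from a specified hazard model (by default the published
final-model estimates: Weibull 0.0022/0.853, age −0.0438/y, AAP 1.39,
CTDD 0.0183/g, ω = 1.01), and the generating parameters and per-subject
frailties are stored as ground truth.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: covariate correlations (dose–age, dose–BMI),
dose titration over time, informative censoring, deterioration states,
and recording artefacts.  One limitation is structural: under the default
generating parameters the cumulative baseline hazard at the mean follow-up
is ≈48, so nearly every synthetic subject improves (and does so hundreds
of times over long follow-up), whereas a real clinic cohort of this kind
records about one improvement per patient with roughly half the patients
never improving.  Those published parameters are internally inconsistent
with that event frequency under this model class; the package keeps them
as defaults because parameter *recovery*, selection operating
characteristics and VPC calibration are unaffected by the absolute event
rate, but absolute event counts from the generator should not be read as
clinically realistic.  The generator's event-frequency consistency is
instead tested against the model-implied improver probability computed by
quadrature.

## Degenerate inputs and edge rules

* Event times are clamped to ≥1e-6 weeks (the Weibull hazard is zero or
  singular at exactly 0); tied event times within a subject are perturbed
  by +1e-6 weeks — weekly recording makes exact ties rounding artefacts,
  and the likelihood needs distinct jump times.
* Gompertz with |θ2| < 1e-12 switches to its constant-hazard limit to
  avoid cancellation; the Weibull shape is constrained to θ2 > −1
  (integrability near zero).
* Covariates are carried forward between records (step functions); the VPC
  grid interpolation therefore equals the covariate path at weekly
  resolution for static covariates.
* A stratum with no subjects is skipped with a warning; an empty dataset,
  a subject without a terminal censor record, or a negative time is a
  validation error.

## Problem sizes used in the automated checks

Simulation-based checks run at deliberately chosen sizes: simulator
calibration at 10⁴–10⁵ subjects (constant hazard), parameter recovery on
20 cohorts of n = 1000, selection operating characteristics on 5 cohorts
of n = 1000 plus smaller screens, and VPC calibration with 200 replicates
over 20 seeds.  These sizes give Monte-Carlo error comfortably below the
asserted tolerances while keeping the default suite fast on one CPU.
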