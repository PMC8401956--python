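# rtte — repeated time-to-event modelling of symptom improvement under clozapine

`rtte` is a Python package for parametric **repeated time-to-event (RTTE)**
analysis of recurrent clinical events — built around the motivating problem
of *time to positive-symptom improvement* in treatment-resistant
schizophrenia-spectrum patients after starting clozapine.  Each patient can
improve, deteriorate and improve again over years of follow-up, so the
outcome is a recurrent event process observed until an end-of-follow-up
censoring time.  The package is aimed at pharmacometricians and
biostatisticians who want this class of model (typically run in NONMEM)
as an open, scriptable, fully testable library.

## The model

The instantaneous rate of improvement for subject *i* at time *t* (weeks
since the first dose) is

```
h_i(t) = h0(t) · exp(η_i) · exp( Σ_k θ_k (x_ik − x̄_k) )
```

* **Baseline hazard** `h0(t)`: constant `θ1`, Gompertz `θ1·exp(θ2·t)`, or
  Weibull `θ1·t^θ2` (zero at t = 0 for θ2 > 0 — a delayed-onset hazard).
* **Frailty** `η_i ~ N(0, ω²)`: a subject-level multiplicative random effect
  on the scale parameter; IIV is reported as `100·√ω²` %.
* **Covariates** enter log-linearly; continuous ones are centred on the
  cohort median (age at 41 years, six-month cumulative clozapine dose CTDD
  at 34 g), so `exp(θ_k)` is an adjusted hazard ratio per covariate unit.

Events follow a nonhomogeneous Poisson process on total time (the clock
does not reset at an event).  Conditional on `η`, a subject's history
contributes `Σ_j log h(t_j) − ∫_0^T h(u) du`; the frailty is integrated out
by the **Laplace approximation**, and models are estimated by maximising
the marginal likelihood (OFV = −2·log L).  Model building follows the
classic pharmacometric workflow:

1. **Base model**: constant vs Gompertz vs Weibull by likelihood-ratio test.
2. **Covariates**: univariate screen, then stepwise forward addition
   (p < 0.05, ΔOFV 3.84) and backward elimination (p < 0.01, ΔOFV 6.63).
3. **Validation**: Kaplan–Meier visual predictive check (observed KM curve
   against pointwise 95% bands from 1000 simulated replicates, overall and
   stratified, e.g. CTDD ≥ 50 g) and sampling-importance resampling (SIR)
   for RSEs and percentile confidence intervals.

Because the original clinic records are not public, the package ships a
**synthetic cohort generator** that reproduces the published cohort
structure (n = 116; age 41.4 ± 12.2 y; 56 % female; daily dose
254 ± 172 mg; follow-up mean 306, range 8–800 weeks; CTDD median 34 g) and
simulates event histories from a specified hazard model, so every stage of
the pipeline is testable end to end with known ground truth.

## Worked example

```python
import rtte
from rtte.likelihood import FitSpec, fit

cohort = rtte.generate(rtte.CohortSpec(), seed=1)          # n = 116 synthetic cohort
res = fit(FitSpec(family="weibull", covariates=("AGE", "AAP", "CTDD"),
                  centers={"AGE": 41.0, "CTDD": 34.0}), cohort.dataset)
print(res.summary_table().round(4).to_string(index=False))
```

prints (this exact run):

```
parameter  estimate  rse_pct    ahr  ci95_lo  ci95_hi
   theta1    0.0024  13.1806    NaN   0.0017   0.0030
   theta2    0.8473   1.5201    NaN   0.8221   0.8725
      AGE   -0.0467  22.3902 0.9544   0.9350   0.9741
      AAP    1.2096  24.0551 3.3521   1.8951   5.9291
     CTDD    0.0110  40.2882 1.0111   1.0023   1.0199
   omega2    1.1522  14.8268    NaN      NaN      NaN
  iiv_pct  107.3388      NaN    NaN      NaN      NaN
```

Reading the table: the Weibull shape `theta2 ≈ 0.85` means the improvement
hazard starts at zero and keeps rising with time on drug; each extra year
of age lowers the hazard by ~5 % (aHR 0.95), a concomitant second atypical
antipsychotic (`AAP`) multiplies it by ~3.4, each gram of six-month
cumulative dose adds ~1 %, and the frailty SD ≈ 1.07 (IIV ~107 %) says
baseline improvement rates differ enormously between patients.  The
estimates recover the generating values (0.0022, 0.853, −0.0438, 1.39,
0.0183, ω = 1.01) within their standard errors.

The same workflow is available from the shell:

```bash
rtte generate --n 116 --seed 1 --out cohort
rtte pipeline --seed 1 --outdir run1     # base models → screen → stepwise →
                                         # final fit → SIR → KM-VPC + plots
```

`run1/` then holds the base-model comparison, screen and stepwise tables,
the final-model summary, SIR summary, tidy VPC curves (CSV), plots, and a
`manifest.json` with the seed and per-stage status.

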