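# silicarisk

Silica-dust exposure assessment and silicosis risk projection for noncoal
mines.

Occupational exposure to crystalline silica dust remains a leading cause of
silicosis among miners, and risk surveillance needs both *qualitative*
ratings (is a work site tolerable, or does it demand intervention?) and
*quantitative* projections (what fraction of today's workforce will develop
silicosis within 10, 20 or 30 years at current dust levels?).  `silicarisk`
implements that full workflow for occupational hygienists and
epidemiologists:

* **Exposure metrics** — 8-hour time-weighted average (TWA) dust
  concentrations from gravimetric filter weights, free-silica content from
  pyrophosphate bulk digestion, silica-dust concentrations, exceedance of
  the Chinese free-silica-dependent OELs and the ACGIH REL
  (0.025 mg/m³ respirable crystalline silica), and cumulative exposure
  (mg/m³·years) from a job exposure matrix.
* **Survival machinery** — Kaplan–Meier estimation, the k-sample log-rank
  test and Cox proportional-hazards regression with Breslow tie handling
  and a Breslow baseline cumulative hazard, written from scratch so the
  exposure–response model can be refit on cohort data with cumulative
  exposure as a time-varying covariate.
* **Risk projection** — closed-form 10/20/30-year cumulative hazard and
  incidence formulas

  ```
  H_tau = H0(tau) · exp(β_g (gender − ḡ) + β_D (D − D̄))
  I_tau = 1 − S0(tau)^exp(β_g (gender − ḡ) + β_D (D − D̄))
  ```

  with shipped published constants for the total-silica model
  (H0 = 0.09/0.27/0.50, S0 = 0.92/0.76/0.61, β = (1.60, 0.07),
  means (0.95, 8.01)) and the respirable-silica model
  (β = (1.58, 0.24), means (0.95, 2.64)).
* **Qualitative rating** — per-sample 5-level ICMM / INDEX risk codes from
  configurable rating tables, the weighted score
  S_weighted = Σ pᵢ·i, its band classification, and the combined
  two-scheme level.
* **Synthetic data** — generators for a retrospective cohort (drawn from
  the proportional-hazards model itself, with a Weibull baseline calibrated
  to the published anchors) and for a cross-sectional dust survey
  (3 days × 3 samples per job, filter weights back-computed so the TWA
  arithmetic inverts the generator exactly).

## Worked example

Project silicosis risk for a male miner exposed at the survey's overall
median silica concentrations (0.39 mg/m³ total, 0.15 mg/m³ respirable),
assuming constant future exposure D(τ) = concentration × τ:

```python
from silicarisk import (TOTAL_DUST_FORMULA, RESPIRABLE_DUST_FORMULA,
                        cumulative_incidence)

for tau in (10, 20, 30):
    i = 100 * cumulative_incidence(TOTAL_DUST_FORMULA, gender=1,
                                   D=0.39 * tau, horizon=tau)
    print(f"I_{tau} (total model, 0.39 mg/m3): {i:.1f}%")
i20 = 100 * cumulative_incidence(RESPIRABLE_DUST_FORMULA, gender=1,
                                 D=0.15 * 20, horizon=20)
print(f"I_20 (respirable model, 0.15 mg/m3): {i20:.1f}%")
```

prints

```
I_10 (total model, 0.39 mg/m3): 6.5%
I_20 (total model, 0.39 mg/m3): 25.4%
I_30 (total model, 0.39 mg/m3): 50.0%
I_20 (respirable model, 0.15 mg/m3): 27.7%
```

i.e. at today's median total-silica level, half of a male workforce would
be expected to develop silicosis within 30 years.  The full pipeline runs
on a synthetic survey end to end:

```python
from silicarisk import RunConfig, run_pipeline

rep = run_pipeline(RunConfig(seed=7, n_mines=20, jobs_per_mine=3))
ov = rep.quantitative.query("stratum == 'overall' and dust == 'total'")
for r in ov.itertuples():
    print(f"horizon {r.horizon:>2} y: H = {r.H_median:.2f} "
          f"({r.H_q1:.2f}-{r.H_q3:.2f}), I = {r.I_median_pct:.1f}% "
          f"({r.I_q1_pct:.1f}-{r.I_q3_pct:.1f})")
```

```
horizon 10 y: H = 0.07 (0.06-0.09), I = 6.2% (5.7-7.8)
horizon 20 y: H = 0.26 (0.22-0.41), I = 23.3% (19.9-34.1)
horizon 30 y: H = 0.60 (0.46-1.19), I = 45.0% (36.7-69.1)
```

H is the projected cumulative hazard and I the cumulative incidence
(percent), each summarised as median (IQR) over the stratum's dust samples.
A `silica-risk` command-line interface wraps the same steps
(`silica-risk simulate survey`, `exposure`, `fit`, `project`,
`assess-qual`, `report`).

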