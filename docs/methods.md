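# Methods

## The exposure–response model

The quantitative core is a Cox proportional-hazards model on the time
scale *years since first silica exposure*: every worker enters at 0 and
exits at silicosis diagnosis (event) or censoring (left/retired/died/end of
follow-up).  Two covariates drive the hazard: the male indicator
(gender ∈ {0, 1}) and cumulative silica exposure D(t) in mg/m³·years.
D is a *time-varying* covariate: each subject carries a piecewise-constant
concentration path and D(t) is its integral, evaluated at every event time
when the partial likelihood is formed.  (A `time_varying=False` switch
freezes D at exit, since source descriptions of such analyses are often
silent on this point; the synthetic generator and the fitter use the same
convention, so parameter recovery is well-posed either way.)

Ties are handled with Breslow's approximation — the simplest scheme
consistent with the Breslow baseline estimator used downstream.  The
partial likelihood is maximised by damped Newton iterations (step halving
whenever a step would decrease the log-likelihood), converging when the
largest score component falls below 1e−8 or the relative log-likelihood
change below 1e−10.  Standard errors come from the inverse observed
information; p-values are two-sided Wald.  A coefficient exceeding 15 in
absolute value aborts with a monotone-likelihood error (on these covariate
scales that corresponds to a hazard ratio above e¹⁵, which only arises
under separation); a covariate constant across subjects is dropped with a
warning.

The baseline cumulative hazard is the Breslow estimator centered at the
analysis-sample covariate means, H0(t) = Σ_{t_j ≤ t} d_j / Σ_{i at risk}
exp((x_i(t_j) − x̄)'β̂), so H0 describes the mean-covariate profile.  A
fit is frozen into a `PredictionFormula` by reading H0 at the 10/20/30-year
horizons and setting S0 = exp(−H0); asking for a horizon beyond the last
event time is an extrapolation error rather than a silent flat-line.

Two published formula sets are shipped as constants: the total-silica
model (baseline H 0.09/0.27/0.50, baseline S 0.92/0.76/0.61, β_gender 1.60,
β_D 0.07, centering means 0.95 and 8.01) and the respirable-silica model
(β_gender 1.58, β_D 0.24, means 0.95 and 2.64, same baselines).  Because
those constants are rounded to 2 decimals, S0 and exp(−H0) disagree by up
to 0.01 (0.92 vs exp(−0.09) = 0.914); the `PredictionFormula` validator
allows exactly that much and no more, and formulas built from a fit satisfy
S0 = exp(−H0) to machine precision.  The printed gender hazard ratio (4.96)
and exp(1.60) = 4.953 likewise agree only in the last printed digit; the
package always reports exp(β) and does not force the printed value.

## Risk projection

Projections assume *constant future exposure*: a sample measured at
concentration c contributes D(τ) = c·τ at horizon τ.  This is the only
reading under which the published overall incidence medians follow from
the published median concentrations (e.g. the respirable model at
0.15 mg/m³ × 20 y = 3.0 mg/m³·years gives I₂₀ = 27.7%), and it is verified
numerically in the acceptance tests.  H and I are evaluated per sample and
summarised per stratum as median and IQR over samples (not over job
means); since both are strictly monotone transforms of the concentration,
the median commutes with the transform, which the tests exploit.  Gender is
fixed to male for projections (the surveyed workforce is ~99% male),
overridable per call.  Incidence is reported in percent to 1 decimal and
hazard to 2 decimals, at render time only.

## Exposure metrics

Air concentrations use the standard gravimetric form c = (m₂ − m₁)·1000 /
(V·t) mg/m³ (filter weights in mg, flow in L/min, duration in minutes),
with the 8-hour TWA Σcᵢ·Tᵢ/8 when a day is split over exposure segments.
Free silica is (m₄ − m₃)/m × 100 from the pyrophosphate digestion; values
above 100% are clamped with a warning.  Pre-1992 respirable concentrations,
where unmeasured, are back-estimated as 0.30 × total + 0.08 and flagged
`respirable_estimated` for audit — note the 0.08 mg/m³ intercept means the
estimate can exceed a very small total, which is why the flag suspends the
respirable ≤ total invariant.

Silica concentrations multiply each air sample's dust concentration by the
free-silica fraction of its *paired* bulk sample: same mine, job and
sampling day, falling back to the job's median free silica across days
when a day's bulk result is missing (the same "same or similar job" logic
as the historical back-estimation).  Air samples resolving to no bulk
result at all abort the run with a pairing error listing the orphans.

OELs depend on the bulk free-silica band: (1.0, 0.7) mg/m³
(total, respirable) for 10–50%, (0.7, 0.3) for >50–80%, (0.5, 0.2) above
80%.  Samples below 10% free silica are not silica dust and are excluded
upstream.  Exceedance comparisons are strict (a concentration equal to its
limit is compliant, per Chinese GBZ practice).  Cumulative exposure sums
JEM-cell silica concentration × years over a worker's non-overlapping job
spells, erroring on any spell year not covered by a JEM cell.

## Qualitative rating

The two rating schemes' internals are deliberately *configuration*, not
code: the published descriptions of the ICMM risk-rating table and the
occupational hazard risk index do not pin down their lookup rules, so
`RatingConfig` ships defensible defaults and validates any replacement for
monotonicity.  Default ICMM: exposure-ratio bands (≤0.1, ≤0.5, ≤1, ≤2, >2)
as likelihood 1–5, multiplied by a consequence class (default 4 — severe
irreversible disease), the product banded at (4, 8, 12, 16) into codes
1–5.  Default INDEX: the same band weights times a hazard-class weight of
3, banded the same way, which makes INDEX systematically a shade more
lenient than ICMM (as the published stratum scores are).  Both defaults
give code 1 at zero exposure and are monotone nondecreasing in the
exposure ratio.

The weighted score S = Σ pᵢ·i is classified by the closed intervals
very low [0, 1.00], low [1.01, 2.00], medium [2.01, 3.00],
high [3.01, 4.00], very high [4.01, 5.00]; scores are rounded to 2
decimals (half away from zero) before banding, which also resolves values
falling in the gaps between interval endpoints (2.004 → 2.00 → low).  The
combined two-scheme level applies the special rule — both scores ≥ 3.01,
or either ≥ 4.01, yields exactly "high" — and otherwise takes the band of
the larger score (the conservative choice consistent with every published
stratum row).  The special rule is applied literally, so a pair like
(2.50, 4.20) combines to "high" even though 4.20 alone bands as
"very high"; both per-scheme bands and the combined level are emitted so
no information is lost.

## Synthetic data

**Cohort.**  The generator draws from the model the fitter assumes.  The
baseline is Weibull, H0(t) = a·t^b, calibrated in closed form through two
published anchors (10 y, 0.09) and (30 y, 0.50), giving b ≈ 1.561 and an
implied H0(20) ≈ 0.266 against the published 0.27 — the two-point fit
reproduces the middle anchor to within rounding, which is the calibration
check.  Per subject: gender ~ Bernoulli(0.95), a constant exposure rate
r ~ lognormal, administrative censoring uniform on the published 1–68-year
follow-up span, and the event time solving H(t|x) = −ln U with
H(t|x) = ∫₀ᵗ h0(u)·exp(β_g(g − ḡ) + β_D(r·u − D̄)) du.  The integral is
accumulated by trapezoid on a 0.1-year grid (the integrand is smooth) and
the crossing refined by bracketed Brent root search with fixed-order
Gauss–Legendre quadrature inside the bracketing cell, to 1e−8 years; a
target not reached by the censoring time is censored there.  Everything is
a pure function of (config, seed) via `numpy.random.default_rng`.

The exposure-rate lognormal (median 0.265 mg/m³ total / 0.088 respirable,
GSD 2.0) was calibrated once, at design time, so the simulated cohort's
mean cumulative exposure at exit matches the published centering constants
(8.01 and 2.64 mg/m³·years) under the published censoring window; with the
coefficients at their published values this yields roughly 40% events,
which is ample for recovery experiments.  Recovery is the generator's
acceptance property: across 50 seeded cohorts of n = 2000, the refitted
coefficients fall within 2 estimated SEs of truth in ≥ 90% of replicates
and the mean refitted baseline H0(20) lies in [0.24, 0.30].

**Survey.**  126 mines with the published category / production-scale /
mining-method mix, ~4 jobs per mine, 3 days × (1 total + 1 respirable +
1 bulk) samples per job.  Total-dust concentrations are lognormal around
the published overall median 1.30 mg/m³ with variance split across
between-mine (log-sd 0.35), between-job (0.40) and day-to-day (0.55)
levels, matching the published overall IQR 0.86–2.48 in spread; the
respirable fraction is a Beta(4.5, 5.5) ratio of its paired total (so a
respirable sample can never exceed its total by construction), and
free-silica content is 10 + 90·Beta(2, 7) percent, centred near the
published overall median 27.6%.  Filter weights are back-computed from the
target concentration and the mode-specific flow/duration (personal
2 L/min × 240 min at mobile sites, area 20 L/min × 45 min at fixed sites),
so the TWA computation inverts the generator to machine precision — a
round-trip identity the tests assert.

What the generators deliberately do *not* emulate: geography, calendar
trends in dust control, diagnosis delay, between-day autocorrelation of
concentrations, and worker-level clustering within jobs.  Passing tests
therefore demonstrate that the pipeline's arithmetic and inference are
correct under the stated statistical structure, not that real surveys obey
that structure.

## Pipeline and exclusions

The pipeline applies the exclusion rules as logged filters before any
statistic: free silica < 10% (not silica dust), total-dust outliers above
a configurable 50 mg/m³ threshold (far above the plausible maximum of
~42 mg/m³ seen in cohort monitoring), and respirable samples exceeding
their paired total, which are dropped together with their site-day
companions.  Every report figure is recomputable from the intermediate
per-sample table; rounding happens only in `render_tables`.  Runs are
deterministic: the same config and seed produce byte-identical rendered
tables.

## Known limitations

* The Cox fitter handles the two-covariate exposure-response design it was
  built for; it is not a general formula interface.
* Projection uncertainty reflects only the exposure distribution (IQR over
  samples), not coefficient standard errors.
* The qualitative defaults are plausible, monotone stand-ins for the two
  published rating schemes, not reconstructions of them; stratum-level
  weighted scores on synthetic surveys are not expected to reproduce the
  published table values.
* Left truncation, competing risks, frailty and interval censoring are out
  of scope; diagnosis dates are treated as exact event times.
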