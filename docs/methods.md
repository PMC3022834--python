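# Methods

## The question and the estimand

After starting combination antiretroviral therapy (cART), CD4 counts rise
fast for about six months and then more slowly.  The quantity of interest is
the *CD4 slope* from six months onward — the rate of change of the CD4 count
in cells/μL per year — and how it depends on the concurrent viral load (VL)
and other time-updated covariates.  The slope at time T is estimated locally
by ordinary least squares over three consecutive CD4 measurements (at T and
its two neighbours), each paired with the nearest VL test within 28 days.
Because VL enters on the log10 scale with a negative coefficient, the model
can be inverted into a clinically readable rule: the largest VL compatible
with keeping the slope above a floor (+20 cells/μL/yr) in each treatment
period.

## The regression model

For slope endpoint j of patient i,

    slope_ij = x_ij' β + b_i + ε_ij,   b_i ~ N(0, σ_b²),   ε_ij ~ N(0, σ_e²).

The random intercept b_i captures between-patient heterogeneity in the
long-term slope; ε absorbs the (large) sampling noise of three-point slopes.
x contains: sex, current age (per decade), disease stage (reference = CDC
category A/B; tuberculosis-ADI; non-TB ADI — an event at or before T sets
the stage, TB taking precedence), haemoglobin (last observation carried
forward; never-tested patients get the cohort baseline median), concurrent
CD4 (per 100 cells/μL), concurrent log10 VL, hepatitis B/C co-infection,
time since cART in half-open periods ((6,12], (12,18], (18,24], >24 months;
months = days/30.4375), and initial-regimen indicators (NNRTI, boosted PI,
abacavir).

**Estimation.**  With λ = σ_b²/σ_e², the marginal covariance of a patient's
residual vector is σ_e²(I + λJ), invertible in closed form.  β and σ_e² are
profiled out analytically, leaving a one-dimensional REML (default) or ML
criterion in log λ, maximised by a coarse grid plus bounded Brent search
(tolerance 1e-10 on the criterion) with an explicit boundary check at λ = 0.
Wald z-tests and 95% CIs (±1.96·SE) come from the GLS covariance
σ_e²(X'V*⁻¹X)⁻¹ at the optimum; categorical blocks are tested jointly with
a Wald chi-square.  Degenerate inputs are flagged rather than failed: a
rank-deficient design raises an error naming the collinear columns, all
singleton groups fall back to pooled OLS with `sigma_b_unidentifiable`, and
an exactly-linear response is flagged `residual_degenerate`.

**Selection.**  Forward stepwise on block Wald p-values with entry level
0.20; after convergence each excluded candidate is refit once on top of the
final model and reported as adjusted-for.  Selection uses Wald tests rather
than likelihood ratios so REML fits with different fixed effects are never
compared directly.

**Left-censoring.**  Sub-detection VL (<400 copies/mL) is stored in the lab
tables as 200 copies/mL but enters the regression (and the generator's CD4
dynamics) censored *at* the detection limit, log10 400 = 2.602.  With
half-limit coding the final model's own mean prediction over a realistic
cohort overshoots the observed late-phase mean slope by ≈ +9 cells/μL/yr;
with limit coding the coefficients, the suppression fractions and the
two-phase means are mutually consistent, and limit coding is the standard
convention for left-censored viral loads.

## The synthetic cohort generator

The generator produces seeded long-format tables (patients, labs, events,
treatment episodes) whose marginal structure matches the cohort the analysis
assumes.  Key defaults, with units and rationale:

- **Demographics**: 74% male; age truncated-normal (36 ± 8.9 y, so the IQR
  is ≈ 30–42); hepatitis B/C 12%; prevalent ADI at initiation 36%, split
  30/70 TB vs non-TB (the split is not reported anywhere and is
  configurable); regimen 63% NNRTI / 15% non-boosted PI / 20% boosted PI;
  abacavir 5%.
- **Baselines**: CD4 log-normal, median 140 cells/μL, log-scale 0.8; VL
  normal on the log10 scale, 4.93 ± 0.96; haemoglobin 14.0 ± 1.3 g/dL with
  a slow per-visit random walk and a true coefficient of zero; 13% of
  patients are never tested for haemoglobin.
- **Visit process**: three early monitoring intervals (log-normal, median
  85 d) then routine intervals (median 220 d, log-scale 0.45), stopping at a
  log-normal follow-up (median 4.2 y).  The early/routine split reflects
  quarterly year-one monitoring and makes the pooled test-spacing median
  ≈ 165 d; it also places the last early visit near day 170 and the first
  routine visit just after the 183-day phase boundary, so early slope
  endpoints are essentially pure fast-phase and the first post-boundary
  triplet carries only ~13 days of fast-phase growth.
- **Viral load**: each patient responds virologically with probability 0.83;
  responders suppress below 400 copies/mL at a uniform 30–90 days.  After
  their first post-6-month visit, suppressed patients lose suppression with
  a per-visit hazard whose initial value is solved numerically from the
  83%/82% suppressed fractions at 6 and 12 months and which grows by ×1.25
  per suppressed visit (accumulating treatment failure); rebound viraemia
  ramps to a low-level set-point (3.5 ± 0.6 log10) over ~200 days.
  Never-suppressed patients settle at a higher set-point (4.25 ± 0.6 log10),
  consistent with return toward the pretreatment level.  VL tests are
  missing at 3% of visits and drawn 1–21 days after the CD4 test at 30% of
  visits, exercising the 28-day pairing window.
- **CD4 dynamics**: a latent CD4 rises at a patient-specific phase-1 slope
  until day 183 — non-responders gain less (mean 110 cells/μL/yr) and the
  responder mean is derived so the marginal mean is exactly 179 — then
  advances by the generating model's linear predictor plus a patient random
  slope b_i ~ N(0, 20²).  Covariates in the predictor are frozen at the most
  recent visit, except the period (time-since-initiation) effect, which is
  averaged piecewise across any period boundary the between-visit segment
  straddles: visits and periods are both ~6 months wide, and freezing the
  period effect would systematically hand each segment the previous
  (higher) period's slope, displacing the realized late-phase mean ≈ +9
  cells/μL/yr above the model's own mean prediction.  Within a single
  period the rule reduces exactly to freezing.  Observed CD4 adds
  N(0, 25²) measurement noise and is floored at 0.
- **Events and treatments**: incident TB at 0.02/person-year and other ADI
  at 0.03/person-year (exponential waiting times); drug-class changes at
  0.2/year and treatment gaps at 0.08/year with log-normal (median 45 d)
  durations, feeding the sensitivity subsets.

The generating coefficients default to the published final model (constant
205.5; female +7.8; age −4.8/decade; TB +26.3; non-TB ADI +12.0;
haemoglobin 0.0; CD4 +1.9/100; VL −40.5/log10; hepatitis −17.7; periods
−21.5/−25.8/−59.1; NNRTI −1.3; boosted PI −3.4; abacavir −5.6).

**What the generator does and does not emulate.**  It reproduces the
marginal baselines, visit spacing, suppression fractions, and the two-phase
slope pattern, and its within/between variance structure is deliberately
modest.  It does not model adherence, pharmacology, mortality or loss to
follow-up, assay-specific VL dynamics, or informative visit timing.
Passing tests on this cohort therefore demonstrate that the pipeline and
estimator behave as specified under the assumed data-generating process,
not that the published coefficient values would be recovered from any real
cohort.

## Known limitation: attenuation of the VL coefficient

Three-point slope endpoints are smoothed across neighbouring visits.  Four
consequences, all measured by the parameter-recovery harness (100 seeded
cohorts of 1500 patients):

1. triplets spanning the 183-day boundary inherit fast-phase growth;
2. rows at a viral rebound mix pre- and post-rebound slopes while carrying
   the post-rebound VL covariate;
3. the CD4 ≥ 0 floor truncates the steepest declines among viraemic
   patients; and
4. the concurrent-CD4 covariate shares measurement error with the slope
   response, and the accumulated random slope makes time-updated CD4 mildly
   endogenous.

Together these attenuate the fitted VL coefficient to a mean of ≈ −35.1
against the generating −40.5 (≈13%, within the ±15% recovery requirement,
with replicate SD ≈ 0.9), while forward selection retains viral load,
period, hepatitis and age in 100/100 replicates.  Because the per-fit
standard error is ≈ 1.0, the 95% CI essentially never covers the generating
value: interval coverage of the instantaneous truth is not a property this
estimator has under these study conditions, and the harness reports the
attenuation rather than hiding it.  The same mechanism implies the
published coefficients themselves describe smoothed, not instantaneous,
slope responses.

## Numerical conventions

- Years = days/365.25; months = days/30.4375; phase boundary at day 183.
- Nearest-VL ties resolve to the earlier VL test; each VL test anchors at
  most one CD4 test; same-day duplicate pairs keep the first.
- Grid display rounds half away from zero to 1 dp; raw values are kept
  internally.  Borderline flags are inclusive (|slope| ≤ 20).
- The threshold solver returns, per period, the largest grid VL with
  predicted slope ≥ target (GRID) or the closed form
  10^((lp_excl_VL − target)/(−β_VL)) (CONTINUOUS); off-grid cases are
  reported as `below_grid_min`/`above_grid_max`.
- All randomness flows from the single config seed through one
  `numpy.random.Generator`; identical config ⇒ byte-identical CSVs.
- Simulation sizes: calibration checks use one cohort of 2000 patients;
  the recovery harness uses 100 cohorts of 1500 patients, roughly the
  published cohort's scale (1676 patients).
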