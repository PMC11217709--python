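# Methods and design notes

This note records the models behind `wearlab`, the defaults and why they
were chosen, the semantics decided where a rule statement was ambiguous,
and what the synthetic cohort does and does not emulate.

## Study geometry the package models

A 6-week living lab: ~25 community-dwelling adults aged 65+ wear a
smartwatch continuously (except while charging) and answer a short chatbot
survey each morning — one greeting item plus two items drawn uniformly
without replacement from an 8-item depression pool (the suicidality item of
the standard 9-item questionnaire is excluded).  A day is coded
symptomatic (1) if any asked depression item is endorsed, 0 if none, and
missing if no response was recorded.  The first week is an adaptation
period and is excluded from analysis.  Observation spans are 8–40 days
(mean ≈ 32.3); day-level missingness is substantial and domain-specific
(defaults: survey 23%, HRV 33.3%, sleep 54.5%, steps 36.9%).

## Sleep scoring

**Window.** Nights are scored in the 1,080-minute window from 6 PM to noon
the next day, keyed by the evening date.  For a participant whose
day/night cycle is reversed the window is 6 AM–midnight of the same date.

**Rescoring cascade** (applied in order, each rule over the output of the
previous):

1. after ≥ 4 minutes of wake, the first minute of a sleep period is
   "adjusted to sleep" — which is vacuous as stated, since that minute is
   already sleep.  The classic actigraphy rescoring literature runs this
   rule the other way (rescore to *wake*).  Both directions are exposed
   (`rule1_direction="as_printed"` (default) | `"webster"`) and the choice
   is recorded in the nightly output; neither is asserted as the intended
   reading.
2. after ≥ 10 minutes of wake, the first 3 minutes of a sleep period are
   rescored to wake;
3. /4. a sleep period < 6 minutes with > 15 minutes of contiguous wake on
   *both* sides is rescored to wake (read as one two-sided rule);
5. a sleep period < 10 minutes with > 20 minutes of wake on both sides is
   rescored to wake.

Within one rule, decisions are simultaneous: every sleep period is judged
against the series as it stood when the rule started.  The alternative
(immediate-effect minute scanning) would cascade rule 2 through an entire
sleep period and is clearly not intended.  Note the cascade is *not*
idempotent: rule 2 re-triggers whenever ≥ 10 wake minutes still precede
sleep after a first pass (`W¹⁰S¹² → W¹³S⁹ → W¹⁶S⁶`), so rescoring is
defined as a single pass.  Rules 3–5 alone are idempotent (tested).

**Missing minutes** break runs: they are neither sleep nor wake, do not
count toward flanking-wake conditions, and are excluded from TST and
awakening counts.  A night with > 20% missing minutes between onset and
offset is flagged invalid.  These are conservative choices the source
procedure leaves unstated.

**Metrics.** Onset = start of the first ≥ 10-minute uninterrupted sleep
run, offset = end of the last; TIB = offset − onset + 1 (inclusive);
TST = asleep minutes within; an *awakening* is a wake run of ≥ 2
consecutive minutes strictly inside (reading "more than 1 minute"
strictly); SFI = awakenings / TST (per minute of sleep — the analysis
model rescales to per 0.01, i.e. per awakening per 100 sleep minutes);
SE = 100·TST/TIB.  A "long fragmentation episode" is a wake run ≥ 5
minutes by default; the metric's defining threshold is not stated in the
source procedure, so it is configurable.

## Heart-rate variability

Minute-level heart rate cannot yield true beat-to-beat intervals.  The
reconstruction — `round(h)` identical intervals of `60000/h` ms per minute
— is an explicit approximation, flagged via a `source="minute_hr"` field
on every derived record: within-minute variability is lost, so SDNN/RMSSD
reflect minute-to-minute variation and the spectrum carries a minute-step
artifact.  Spectral behavior is therefore validated on synthetic
beat-level series (the generator can emit these directly), not on the
reconstruction.

Filtering removes intervals outside 300–2000 ms, then intervals deviating
more than 20% from a centered 11-point running median.  Windows are
non-overlapping, clock-aligned, 5 minutes long, and need ≥ 30 filtered
intervals to be valid.  SDNN uses the population convention (divide by n).
Band edges follow the standard HRV task-force partition: VLF
0.0033–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.40 Hz; powers are trapezoidal
integrals of a boxcar periodogram of the 4 Hz cubic-spline-resampled,
mean-removed interval series.  The ratio is stored as LF/HF.  Daily
summaries are unweighted means over valid windows.

## Feedback and alerts

Baselines are fixed after week 1 (not rolling): mean and sample SD (n−1)
of each domain's daily values over the participant's first 7 calendar
days, requiring ≥ 2 non-missing days.  Colors: green above mean+SD,
red below mean−SD, yellow within — with the band boundaries assigned to
yellow ("within ±1 SD"), and green/red swapped for the sleep domain, which
is keyed on the fragmentation index (total sleep time is displayed but not
colored).  The stress domain is keyed on daily mean HF power with higher =
green, implementing the stated rule as-is; whether higher HF was *meant*
as good is an open interpretive question we do not resolve.  Steps and
activity are separate domains (daily step count vs. summed
light+moderate+intense minutes).

Emergency triggers are strict inequalities evaluated independently per
day: inactive run > 480 minutes, any minute HR < 30 bpm, any minute
HR > 140 bpm; one alert per trigger per day at the first crossing.
Minutes with missing data count as inactive by default (a device that is
off could itself be an emergency) — configurable in the activity
aggregator.

## The multilevel model

Each predictor is fit alone (plus covariates):

    logit P(y_ij) = β0 + β1·(x_ij − x̄_i) + γ'z_i + u_i,  u_i ~ N(0, σ²)

- Person means x̄_i are computed over the analysis weeks (week 1 excluded),
  so centered predictors average to zero within person on complete data.
- Covariates (age, sex, chronic-disease count, baseline depression score)
  are grand-mean centered over the participants present.
- Estimation is by maximum marginal likelihood.  The integral over u_i
  uses *adaptive* Gauss–Hermite quadrature: per cluster, a Newton search
  finds the mode of the integrand and its curvature, and 10 Hermite nodes
  (configurable) are centered and scaled there; one node reproduces the
  Laplace approximation, which is the fallback when the full optimization
  fails.  The estimator matches `lme4::glmer` (nAGQ=10) to ~1e-3 on
  coefficients, standard errors, and σ in the cross-check test.
- Inference is Wald on the log-odds scale (CIs exponentiated); the
  numerically differentiated Hessian of the marginal log-likelihood
  supplies standard errors.  Coefficients with |β| > 15 are reported as
  probable complete separation with `converged=False`, never as silent
  estimates.
- Missing data are handled available-case per model (each model drops
  rows missing its predictor or outcome); with a single level-1 predictor
  per model this is operationally what full-information estimation gives,
  and no imputation is performed.
- The SFI enters the model per 0.01 units; efficiency per percentage
  point; all other predictors in their native units.

The battery is 11 predictors × 2 outcomes (same-day, next-day).  The
same-day outcome is predicted by the night *ending that morning* — the
convention the generator also uses — so "same-day" sleep effects are
previous-night effects on the day's report.  Holm–Bonferroni runs within
each 11-test outcome family at α=0.05 (implemented step-down by hand so a
family size larger than the supplied vector can be used; verified against
statsmodels); a fixed 0.005 threshold is reported alongside.

Pre/post comparisons: exact Wilcoxon signed-rank (zero differences
dropped, mid-ranks for ties, normal approximation when ties preclude the
exact distribution) with a Hodges–Lehmann median-difference interval from
Walsh averages and exact signed-rank critical values; paired t for
usability; 2×2 mixed ANOVA (time × age group, "oldest" = strictly over
75) for age moderation.  Group descriptives use Welch t tests for
continuous variables and chi-square for categorical, falling back to the
exact hypergeometric test for 2×2 tables with small expected counts; the
depression risk group is a baseline score ≥ 5.

## The synthetic cohort

The generator's defaults *are* the study conditions; distributional forms
are artifact choices, set once from the cohort's descriptive moments and
documented here.

- **Profiles**: age ~ round N(76.4, 4.23) clipped at 65; 76% women;
  4-level education/income categoricals at the observed proportions;
  chronic conditions ~ Poisson(4.2); baseline depression ~ round
  N(4, 3) on 0–15 (≈ 40% at the ≥ 5 cutoff); sleep-quality index ~ round
  N(8.3, 2.5) on 0–21; usability ~ N(53.3, 24.5) pre with a ~+6 post
  shift; exactly one reversed-cycle sleeper by default.
- **Nights** are constructed, not drawn: bedtime ≈ 4 h into the window
  (10 PM), time in bed ~ N(485, ~60) min, a Poisson number of awakenings
  (person rate lognormal around 6.5) with lognormal durations (median
  ≈ 20 min).  The night is then **scored by the package's own sleep
  module**, and the scored SFI/SE/TST are the night's true covariates.
  This keeps generator and analysis internally consistent: the target
  cohort means (TST ≈ 320 min, SE ≈ 66%, SFI ≈ 0.02) imply few, *long*
  awakenings, which necessarily interact with rescoring rule 2, so
  independently drawn "true" metrics would not survive scoring.
- **Symptoms**: logit(p) = α_i + β_sfi·SFI100_c + β_se·SE_c, with the
  night ending that morning as the driver (configurable to the same
  evening's night).  Centering uses the person's *expanding* mean over
  nights seen so far — the person's true mean is unknown mid-stream —
  which converges to the analysis-time centering; a `true_mean` switch
  exists.  The person intercept α_i (SD 1.0 on the logit scale) loads
  0.4 on standardized baseline depression and 0.35 on the person's
  awakening-rate factor, giving the observed person-level correlations of
  symptoms with baseline depression and with sleep quality; its level is
  calibrated by a logit-normal approximation so the marginal symptom rate
  is ≈ 0.37 (accurate to a couple of points).  Default coupling odds
  ratios are 2.066 per 0.01 SFI and 0.972 per % SE.
- **HRV and activity daily summaries** are drawn from person-level normal
  and lognormal distributions matched to the cohort descriptives (LF/HF
  5.94 ± 1.33, SDNN 103 ± 42, RMSSD 9.3 ± 3.9, HF ≈ 26 ms²; steps
  lognormal with mean ≈ 3200; light/moderate/intense ≈ 130/14/22 min);
  they carry **no** symptom coupling and act as the null predictors.
- **Minute rendering** (optional; what the pipeline consumes) places the
  same scored night structures on the clock, adds a circadian heart-rate
  sinusoid (person mean ≈ 72 bpm, amplitude 5, sleep dip 8, noise 2.5,
  clipped to 40–120 bpm), one step bout per daytime 2-hour slot summing to
  the day's step total, a few steps at the start of each nocturnal
  awakening (getting out of bed registers on the sensor — this is what
  keeps healthy nights below the 8-hour inactivity threshold), and
  device-style intensity classes from per-minute step counts.  Streams
  begin at 6 AM of the install day (the day before the first survey), so
  every day, including the first, has a preceding scored night.
- **Missingness** is day-level and missing-completely-at-random,
  independent per domain (survey, HRV, sleep, steps) — matching the
  observed marginal rates under the weakest assumption, since only
  marginal day counts are known.  An `exact=True` mode masks exactly
  `round(rate·n_days)` days (sampling without replacement) so realized
  proportions equal the configured rates by construction.  Symptoms are
  generated on complete data first; masking only hides them, so MCAR
  holds exactly.

What the generator does **not** emulate: autocorrelated or
missing-not-at-random wear gaps, within-minute heart-beat dynamics
(beat-level series are available separately for spectral tests), seasonal
or weekday structure, device-specific classification error, and any
coupling of HRV/activity to symptoms.  Passing tests therefore demonstrate
that the pipeline recovers known structure under realistic geometry and
MCAR missingness — not that real sensor data meet those assumptions.

## Monte-Carlo experiments and problem sizes

Parameter recovery (in `wearlab.recovery` and `scripts/acceptance.py`)
uses 200 replicates of 25 × 33-day cohorts per target, generated in
day-level mode (nights constructed and scored at run-length level; minutes
are not rendered — the minute path yields identical nightly metrics by
construction and is tested for exactly that).  Only the target predictor
carries coupling in each experiment, so the single-predictor analysis
model is correctly specified.  With missingness and the excluded first
week, each replicate fits on ≈ 230 days from 25 participants, and the
mean fitted OR recovers the generating value with a Monte-Carlo SE of
≈ 0.02 (fragmentation) and ≈ 0.001 (efficiency).  Two small opposing
finite-sample effects are visible at this scale: expanding-mean generation
vs. full-mean analysis centering attenuates the log-odds by a few percent,
while small-sample ML bias pushes away from the null.  Type-I calibration
uses 500 null replicates of the same geometry.

## Numerical choices and degenerate inputs

- Sample SD (n−1) for feedback baselines; population SD for SDNN; both
  deliberate and tested.
- A baseline with SD 0 (constant week) leaves a zero-width yellow band:
  the exact baseline value is yellow, anything else green/red.
- Zero TST or no ≥ 10-minute sleep run → night invalid, never an
  exception; all-zero pre/post differences → Wilcoxon reported undefined;
  identical pre/post → paired t statistic 0, p 1.
- Quadrature default 10 nodes; L-BFGS-B over (β, log σ) with
  log σ ∈ [log 1e-4, log 50]; pooled ridge-stabilized logistic start
  values.
- The pipeline manifest hashes every emitted table; configuration paths
  are excluded from the hash so identical data and seed give identical
  manifests regardless of output location.
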