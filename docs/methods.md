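# Methods

This note documents the models behind `concern_ews`: what the synthetic
cohort generator assumes, how the features, scores and evaluation
statistics are defined, the numerical choices that matter, and what the
package's passing tests do and do not establish about real ward data.

## The synthetic cohort generator

### What it emulates

The generator produces the three tables a real study would extract from a
clinical information system: encounters (demographics, unit, admission
and discharge times), a timestamped event stream of clinician–CIS
interactions, and composite-outcome events. Its defining assumption is a
*temporal decoupling* between two latent processes attached to each
deteriorating encounter:

* **Concern ramp `c(t)`** — rises from 0 at `event − behavioral_onset_hours`
  (default 48 h) to its per-encounter gain at the event, linearly by
  default (a logistic option exists). It multiplies the intensity of
  every documentation channel: `λ_f(t) = λ_f · w(hod) · (1 + β_f · c(t))`,
  with default multipliers `β_f = 3` (4× rate at full concern).
* **Physiological drift `d(t)`** — rises from 0 at
  `event − physiological_onset_hours` (default 6 h) to 1 at the event. It
  moves the mean of each vital-sign value from a calm center toward an
  abnormal target (tachycardia, tachypnea, hypotension, fever,
  desaturation), flags supplemental oxygen on SpO2 entries when
  `d > 0.5`, and leaves documentation *rates* untouched.

Both ramps are evaluated at hour-bin midpoints on a 1-hour, left-closed
grid; within-bin event times are uniform. Admissions fall on whole hours
so bin boundaries align with the wall clock.

Baseline intensities follow the standard-of-care rhythm: routine vitals
(all five kinds, one charting action) are forced at the q4h schedule
`{0, 4, 8, 12, 16, 20}`, and 90% of discretionary documentation mass
falls in those hours (`schedule_mass`). The per-channel baseline rates
(a few discretionary vital rechecks per day, rarer flowsheet comments,
~3 notes/day, occasional PRN administrations and withheld scheduled
medications) are stated assumptions chosen to resemble an acute-care
med-surg unit; no public rate tables exist for the populations this kind
of study draws on.

### Heterogeneity and noise

Four mixtures keep the cohort from being unrealistically clean — each is
also necessary for the evaluation models to be well posed (perfectly
deterministic signals produce separated partial likelihoods and infinite
hazard ratios):

* per-encounter **concern gain** ~ U(0.3, 1.0): nurses escalate to
  different degrees;
* **unanticipated deteriorations** (15%): no concern ramp at all;
* **sudden events** (15%, independent): no vital drift before the event
  (arrhythmia/embolism-like);
* **sick-but-stable patients** (10%): persistent chronic shifts
  (severity U(0.2, 0.7) on a random subset of vitals), holding sustained
  moderate/high comparator-score exposure without deteriorating; plus a
  2% per-measurement mildly-abnormal outlier rate.

### Outcomes and censoring

Every encounter carries a constant deterioration hazard; an event occurs
iff an exponential candidate time lands within the stay (truncated at
98% of the stay, floored at 2 h), with the hazard calibrated so the
expected event share equals `event_fraction` (default 0.10). This
memoryless construction matters: given survival to hour *t*, the
probability of an event in any future window is constant in *t*, so time
since admission carries no artificial predictive signal and null
simulations are genuinely null. Event encounters end at their first
component event (mortality, cardiac arrest, ICU transfer, rapid
response, sepsis, with a plausible mix); others are right-censored at
discharge. Lengths of stay are lognormal (median 96 h, σ = 0.6); ages
truncated normal (64 ± 16, floor 16, so a small under-18 tail exercises
the filters). Back-charting (retrospective batch entry) is not simulated.

Determinism: a single `numpy` Generator seeded from the config drives all
draws in fixed order, so identical (config, seed) pairs produce
byte-identical tables.

## Feature extraction

Rows are fully observed patient-hours: the partial bin truncated by the
event or discharge is dropped, exactly as discrete-time survival analysis
uses complete person-periods. (Keeping it systematically undercounts the
trailing window on precisely the rows nearest the outcome — a subtle
label leak the null-calibration tests caught.)

The 55 columns are:

* 15 base features × {common, uncommon} = 30: five vital-measurement
  counts, five flowsheet-comment counts, PRN administrations, withheld
  scheduled medications, notes written, plus two derived vitals-pattern
  features — occurrences of *all five vitals charted in one 5-minute bin*
  and of a *vitals-taking episode containing exactly one measurement*
  (an episode is a maximal run of measurements with gaps under
  15 minutes). Both cutoffs are stated assumptions: "the same time" is
  taken to mean one charting action, and episode membership one visit to
  the bedside. The derived features are counts of qualifying occurrences
  rather than 0/1 indicators so that the common/uncommon partition
  identity (common + uncommon = total) holds for all 15 base features.
* 21 nursing-note concept counts over a fixed vocabulary (abdominal pain
  … violence gesture); synthetic notes carry the tags directly, since
  concept extraction from real free text is a separate problem.
* 4 temporal features: month (1–12), day of week (0–6, Monday = 0), hour
  (0–23), patient hour (hours since admission).

All counts are trailing `window_hours` (default 12) sums, closed on the
right at the row's hour end, so every row is computable prospectively.
Common hours are learned per feature as the hours of day holding at
least `1/24` of that feature's events (pooled across units; with fewer
than 100 events the configured schedule is used and a warning logged).
The two derived features share the pooled vital-measurement profile.

Inclusion filters follow the usual cohort definition literally: more
than 24 h on a study unit (strict), age ≥ 18, not hospice, stay not
exceeding 60 days (a stay of exactly 60 days is retained). A per-rule
exclusion tally is reported; an encounter violating several rules counts
under each.

## Scoring

**Behavioral scorer.** A pooled per patient-hour logistic regression of
"first composite event within the next H hours" (H = 12 by default) on
the standardized 55 features, L2-regularized (strength 1.0 on the
standardized scale — also the guard against separation in small
cohorts). Train/test splits are always by encounter, never by row. The
continuous score is the linear predictor; categories come from cutpoints
at the 0.80/0.95 quantiles of the training-score distribution
(green/yellow/red ↔ low/moderate/high). Quantile cutpoints are a
documented, reproducible stand-in for production categorical mappings,
which are typically tuned to clinician feedback and unpublished.

**Comparators.** MEWS (systolic BP, heart rate, respiratory rate,
temperature, AVPU; integer range 0–14) and NEWS (respiratory rate, SpO2,
supplemental O2, temperature, systolic BP, heart rate, consciousness;
0–20) are computed from the standard published component tables, bundled
as versioned YAML files with provenance headers (Subbe 2001; RCP 2012).
Urine output is omitted from MEWS (not charted hourly here); the NEWS
variant is the 2012 original. Category bands: MEWS low 0–2 / moderate
3–4 / high 5+; NEWS low 0–3 / moderate 4–6 / high 7+. Hourly values are
last-observation-carried-forward with a 12-hour staleness limit; hours
before the first complete vitals set (or past the staleness limit) carry
an undefined score, emitted as missing and excluded from models.
Consciousness is treated as Alert when scoring from event streams — the
stream carries no AVPU channel; the per-row `mews_total`/`news_total`
functions accept explicit AVPU input.

## Evaluation

**Counting process and Cox model.** Hourly categories are run-length
encoded into `(start, stop]` intervals with indicator covariates
(`*_moderate`, `*_high`; low is the reference), complete-case across the
requested systems. The event attaches to the interval containing the
first event time; when the grid ends at the last full hour, the final
covariate is carried into the event hour. Fits use
`lifelines.CoxTimeVaryingFitter` (Efron ties, Wald 95% CIs on the log-HR
scale). Full Newton steps can overshoot when hazard ratios are large, so
the fit retries with damped steps (0.95 → 0.3 → 0.1) — same optimum,
safer path. The pipeline additionally falls back to a light ridge
penalty (0.01, then 0.1) when a multi-indicator model is near-separated
at small cohort sizes, recording the penalizer in the manifest.

**Lead-time likelihood ratio.** For level x and horizon h,
`L(x, h) = P(x | event in hour bin t + h) / P(x | no event at t + h)`.
The default *exact-horizon* convention places the numerator at hours
exactly h before the event bin (one hour per event encounter per h); a
*cumulative* convention (event within `(t, t+h]`) is available. The
denominator pools hours whose status at `t + h` is known to be
event-free; hours within h of censoring are excluded (their status is
unobserved). Both conditional frequency tables receive add-k smoothing
(k = 0.5) before the ratio, which keeps `L > 0` and `log L` finite.

The **warning horizon** summarizes a curve as the last horizon before
`log L(high, h)` first falls below `log 1.5` scanning outward from the
event — the length of the contiguous near-event window over which the
high level shifts the odds of an upcoming event by ≥ 1.5×. Two guards
make this an estimator rather than an artifact: isolated exceedances at
distant horizons do not extend the run, and a horizon counts only if the
level was observed in at least 3 pre-event patient-hours — with add-k
smoothing, a level unobserved (or observed once) in a small numerator
otherwise yields a floor ratio that can sit above the threshold
indefinitely against a rarely-elevated comparator, the same reason
chi-square practice distrusts cells with tiny expected counts.

## Problem sizes and what the tests show

The test suite exercises the pipeline at desk scale: unit tests on toy
tables and cohorts of 40–300 encounters; null-calibration at 50
replicates of 500 encounters with 5-fold cross-fitted scores;
parameter recovery at 20 replicates each of 200 and 2,000 encounters
against a planted 5× hazard ratio; lead-time ordering at 10 seeds of
1,500 encounters. These sizes were chosen so the full suite runs in
minutes on one CPU.

Passing tests establish that the *pipeline* is correct and calibrated:
window counts equal brute-force rescans, comparator totals equal
independent table lookups, the Cox fit matches a hand-derived closed
form and recovers planted hazard ratios, null simulations yield hazard
ratios near 1, and the built-in 48 h-vs-6 h onset gap is recovered as a
large behavioral lead-time margin. They do not establish that real
nursing documentation carries such signals — the generator encodes that
hypothesis rather than testing it — nor how strong real-world effects
would be: synthetic effect sizes here are cleaner than EHR reality
(no back-charting, no inter-site dialects, no documentation-burden
confounds, hour-aligned admissions, tag-level note concepts).

One caveat on the null-calibration statistic: at the 50 × 500 scale the
pooled numerator of the lead-time ratio holds roughly 2,400
patient-hours, of which the high band holds ~5%, so the sampling noise
of `log L(high, ·)` is ≈ 0.1 — of the same order as the band the
calibration check targets. A benchmark replacing the fitted scores with
independently drawn random categories lands in the same range, so values
there should be read against that noise floor, not as evidence of
miscalibration.
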