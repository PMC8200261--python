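# Pipeline configuration template.
#
# Run with:  concern-ews run --config pipeline_config.yaml --out out/
# Any omitted key keeps its documented default; unknown keys are rejected.

# Global seed; fans out deterministically to per-stage substreams.
seed: 0

sim:
  n_encounters: 500
  # Expected share of encounters reaching the composite outcome.  Events
  # are generated memorylessly (constant deterioration hazard calibrated
  # to this share over the realized stays).
  event_fraction: 0.10
  # Hours before the event at which the latent concern ramp / the vital
  # drift ramp begin.  Behavioral onset must not precede physiological.
  behavioral_onset_hours: 48
  physiological_onset_hours: 6
  # Routine charting schedule (wall-clock hours); empty list disables
  # forced vitals and flattens the hour-of-day weights.
  vitals_schedule: [0, 4, 8, 12, 16, 20]
  # Fraction of baseline discretionary documentation falling in the
  # scheduled hours.
  schedule_mass: 0.9
  # Per-channel baseline rates (events/hour) and concern multipliers may
  # be overridden per channel, e.g.:
  # base_rates: {note_written: 0.12, hr_comment: 0.02}
  # concern_multipliers: {note_written: 3.0}
  # Length-of-stay: lognormal, in hours.
  los_distribution: {median_hours: 96, sigma: 0.6, min_hours: 30, max_hours: 1500}
  age_distribution: {mean: 64, sd: 16, min: 16, max: 100}
  concern_ramp: linear        # or sigmoid
  drift_scale: 1.0            # 0 disables vital drift (null simulations)

features:
  window_hours: 12            # trailing aggregation window
  common_threshold: 0.0416667 # hour-of-day share >= 1/24 counts as common
  min_events_for_profile: 100

scoring:
  horizon_hours: 12           # "event within next H hours" training label
  cutpoint_quantiles: [0.80, 0.95]  # yellow / red cutpoints
  train_fraction: 0.5         # encounter-level train/test split
  l2_strength: 1.0
  staleness_hours: 12         # carry-forward limit for comparator vitals

evaluation:
  horizons: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
             19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34,
             35, 36, 37, 38, 39, 40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 50,
             51, 52, 53, 54, 55, 56, 57, 58, 59, 60]
  smoothing: 0.5              # add-k smoothing of the level frequencies
  horizon_convention: exact   # or cumulative ("event within (t, t+h]")
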