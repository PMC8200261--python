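"""Apply cohort inclusion filters and build the hourly feature matrix.

The matrix has one row per fully observed patient-hour and 55 columns:
15 base documentation features split into common/uncommon charting hours
(30), 21 nursing-note concept counts, and 4 temporal features.  Counts
are trailing 12-hour window sums.
"""

from concern_ews import (
    SimConfig,
    apply_inclusion_filters,
    build_hourly_features,
    learn_all_profiles,
    simulate_cohort,
)
from concern_ews.features import measurement_columns, note_columns

encounters, events, outcomes = simulate_cohort(SimConfig(n_encounters=200, seed=5))

filtered, tally = apply_inclusion_filters(encounters)
print(f"inclusion filters retained {len(filtered)}/{len(encounters)} encounters")
print(f"exclusions by rule: {tally}")

kept = events[events["encounter_id"].isin(set(filtered["encounter_id"]))]
profiles = learn_all_profiles(kept)
print("\ncommon charting hours learned for heart-rate measurement:",
      sorted(profiles["hr_measurement"].common_hours))

matrix = build_hourly_features(kept, filtered, profiles, outcomes=outcomes)
print(f"\nfeature matrix: {len(matrix)} patient-hours x "
      f"{matrix.shape[1] - 1} features "
      f"({len(measurement_columns())} measurement, {len(note_columns())} note, 4 temporal)")

row = matrix.iloc[200]
print(f"\nexample row (encounter {row['encounter_id']}, hour {row['patient_hour']}):")
print("  HR measurements in trailing 12 h (common/uncommon hours):",
      row["hr_measurement_common"], "/", row["hr_measurement_uncommon"])
print("  notes written:", row["note_written_common"] + row["note_written_uncommon"],
      " pain-level concepts tagged:", row["pain_level"])
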