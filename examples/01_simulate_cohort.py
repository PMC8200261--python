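"""Simulate a synthetic ward cohort of clinician-EHR interaction streams.

Generates encounters, a timestamped event stream (vital measurements and
comments, PRN administrations, withheld scheduled medications, nursing
notes with concept tags), and composite deterioration outcomes, then
prints cohort-level summaries.
"""

import pandas as pd

from concern_ews import SimConfig, simulate_cohort

config = SimConfig(n_encounters=300, seed=11)
encounters, events, outcomes = simulate_cohort(config)

stay_h = (
    pd.to_datetime(encounters["discharge_time"])
    - pd.to_datetime(encounters["admit_time"])
) / pd.Timedelta(hours=1)

print(f"encounters: {len(encounters)}  (median stay {stay_h.median():.0f} h)")
print(f"events:     {len(events)} rows")
print(events["event_type"].value_counts().to_string())
print(f"\noutcomes:   {len(outcomes)} encounters reach the composite endpoint")
print(outcomes["component"].value_counts().to_string())

# Documentation intensity rises before events: compare the discretionary
# event rate in the 48 h before an event with the cohort baseline.
first = outcomes.set_index("encounter_id")["event_time"]
disc = events[events["event_type"] != "vital_measurement"].copy()
h = (
    pd.to_datetime(disc["timestamp"])
    - pd.to_datetime(disc["encounter_id"].map(encounters.set_index("encounter_id")["admit_time"]))
) / pd.Timedelta(hours=1)
to_event = disc["encounter_id"].map(first) - h
pre = ((to_event > 0) & (to_event <= 48)).sum()
pre_hours = first.clip(upper=48).sum()
base_rate = len(disc) / stay_h.sum()
print(f"\ndiscretionary documentation: {pre / pre_hours:.3f}/h in the 48 h "
      f"pre-event vs {base_rate:.3f}/h overall")
print("The excess reflects the latent concern ramp that begins ~48 h before "
      "deterioration, long before vital signs drift.")
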