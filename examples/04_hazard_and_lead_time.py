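"""Evaluate hourly risk scores with a time-varying Cox model and the
lead-time likelihood-ratio statistic.

Runs the full pipeline on a default cohort, then prints the forest-plot
numbers (hazard of the composite outcome in moderate/high score states
relative to low) and the warning horizons implied by the lead-time
curves L(x, h) = P(x | event h hours ahead) / P(x | no event h hours ahead).
"""

import tempfile

import pandas as pd

from concern_ews import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(sim=SimConfig(n_encounters=800), seed=7)
with tempfile.TemporaryDirectory() as tmp:
    manifest = run_pipeline(config, tmp)
    hazards = pd.read_csv(f"{tmp}/hazards.csv")

print("time-varying Cox hazard ratios (low risk = reference):")
for _, r in hazards.iterrows():
    print(f"  {r['model']:>12}  {r['covariate']:<18} "
          f"HR {r['hr']:7.2f}  (95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f})  "
          f"excess hazard {r['excess_hazard']:+.2f}")

print("\nwarning horizons (largest h with sustained log L(high, h) > log 1.5):")
for system, h in manifest["warning_horizons"].items():
    print(f"  {system:>8}: {h} hours before the event")
gap = manifest["warning_horizons"]["CONCERN"] - max(
    manifest["warning_horizons"]["MEWS"], manifest["warning_horizons"]["NEWS"]
)
print(f"\nThe behavioral score separates event from non-event patients "
      f"{gap} hours earlier than the best physiology-based comparator.")
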