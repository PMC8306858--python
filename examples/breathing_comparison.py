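"""Effect of the breathing state on the ablation outcome.

Runs the four study frequencies for inflated and deflated lung properties
(coarse grid for speed) and prints the per-frequency contrasts: peak
temperature, peak SAR, and how the necrosis timing shifts.  These are the
quantities that make respiratory motion matter for treatment planning.
"""

from mwablate.study import StudyConfig, compare_states, run_study

cfg = StudyConfig(states=("inflated", "deflated")).fast()
result = run_study(cfg)

cols = ["frequency_hz", "state", "T_max_final", "SAR_max",
        "saturation_time_s", "time_to_full_necrosis_s", "zone_aspect"]
print(result.records[cols].to_string(index=False,
      float_format=lambda x: f"{x:.6g}"))

print("\nper-frequency relative differences between states "
      "(|a-b|/max(a,b) x 100):")
print(compare_states(result).to_string(index=False,
      float_format=lambda x: f"{x:.3g}"))

print("\nReading: the deflated (denser, lossier) lung absorbs more compactly; "
      "near the design frequency it heats slightly hotter and its zone is "
      "rounder, while at lower frequencies feed mismatch reduces its "
      "deposited power.")
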