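"""Reproduce the two device-storage loss signatures in dispersion tables.

A flash glucose sensor holds 8 h of data and loses the oldest samples unless
the wearer scans it; nobody scans while asleep, so loss piles up at the start
of the night. A wrist tracker's memory fills after ~5 days of dual-stream
recording and step recording simply stops until the day-7 clinic sync clears
it, so measurement days 6-7 are lost outright.
"""
import numpy as np

from wearmiss import (
    AnalysisConfig,
    MechanismSpec,
    analyze_dispersion,
    preprocess_cohort,
    simulate_cohort,
)
from wearmiss.simulate import cgm_device, scenario

cfg = AnalysisConfig()

# --- CGM: 8-h FIFO buffer, wake-only manual scans ------------------------
cohort = simulate_cohort(
    30, seed=5, modalities=("glucose",),
    mechanisms={"glucose": MechanismSpec("buffer")},
    devices={"glucose": cgm_device()},
)
recordings, _ = preprocess_cohort(cohort.raw, cfg)
disp = analyze_dispersion(recordings["glucose"], "hour_of_day", cfg)
peak = int(np.nanargmax(disp.medians))
print("glucose, hour-of-day dispersion (median % missing per clock hour):")
print("  hours 20..03:",
      np.round(disp.medians[[20, 21, 22, 23, 0, 1, 2, 3]], 1).tolist())
print(f"  peak at {peak:02d}:00; Kruskal-Wallis p = {disp.kw_p:.3g}; "
      f"{len(disp.significant_pairs)} Bonferroni-significant Dunn pairs")
print("  -> loss concentrates right after sleep onset: the night exceeds the")
print("     8-h buffer plus the wait until the first morning scan.")
print()

# --- tracker: stop-when-full storage, cleared at the day-7 visit ----------
cohort = simulate_cohort(30, seed=5, modalities=("hr", "steps"),
                         **scenario("tracker_overflow"))
recordings, _ = preprocess_cohort(cohort.raw, cfg)
disp = analyze_dispersion(recordings["steps"], "measurement_day", cfg)
print("steps, measurement-day dispersion (median % missing per day):")
print("  days 1..13:", np.round(disp.medians, 1).tolist())
n67 = sum(1 for a, b, _ in disp.significant_pairs
          if {"day 6", "day 7"} & {a, b})
print(f"  Kruskal-Wallis p = {disp.kw_p:.3g}; {n67} significant pairs involve "
      f"days 6-7")
print("  -> storage fills during day 6 and step recording stops until the")
print("     day-7 clinic sync; the recording also ends ~day 12 when it fills")
print("     again before the final visit.")
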