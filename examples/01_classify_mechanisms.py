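"""Classify the missingness mechanism of simulated wearable cohorts.

Builds three 20-subject, 14-day heart-rate cohorts with known injected
missingness (uniform random dropout, night-weighted dropout, heavy-tailed
device gaps), runs the two-step screen on each and prints the verdict next to
the ground truth.
"""
import numpy as np

from wearmiss import AnalysisConfig, preprocess_cohort, simulate_cohort
from wearmiss.cohort import analyze_modality
from wearmiss.simulate import scenario

cfg = AnalysisConfig()
truths = {"mcar": "MCAR", "mar_night": "MAR", "mnar_zipf": "MNAR"}

print(f"{'scenario':<12} {'truth':<6} {'verdict':<8} {'step1':<8} {'step2':<6} "
      f"{'gaps':>6} {'Planck p':>9} {'loss %':>7}")
for name, truth in truths.items():
    cohort = simulate_cohort(20, seed=7, modalities=("hr",), **scenario(name))
    recordings, _ = preprocess_cohort(cohort.raw, cfg)
    a = analyze_modality(recordings["hr"], cfg, families=("planck",))
    loss = float(np.mean([r.percent_missing for r in recordings["hr"]]))
    print(f"{name:<12} {truth:<6} {a.verdict.final:<8} {a.step1:<8} {a.step2:<6} "
          f"{a.freq.total_gaps:>6} {a.planck_fit.chi2_p:>9.3g} {loss:>7.1f}")

print()
print("Step 1 tests the pooled gap-size table against a fitted Planck")
print("(discrete exponential) pmf: a significant departure means the gaps are")
print("not produced by a random process (MNAR). Step 2 tests per-subject")
print("percent-missing across time groups with Kruskal-Wallis + Dunn:")
print("a surviving pair means time-dependent loss (MAR); otherwise MCAR.")
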