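# wearmiss

Missing-data statistics for wearable-sensor time series: modality-specific
missingness definitions, gap-size distribution fitting, missing-data
dispersion testing, and MCAR / MAR / MNAR mechanism classification — plus a
synthetic cohort generator whose mechanistic missingness injectors (device
storage buffers, synchronisation behaviour, time-dependent and heavy-tailed
dropout) make every stage of the analysis testable against a known ground
truth.

## Who this is for

Free-living health-monitoring studies — continuous glucose monitoring (CGM),
wrist trackers recording heart rate (HR) and step count — inevitably lose
data: sensors detach, on-device memory fills, participants forget to scan or
synchronise. Knowing *why* data went missing matters: the mechanism decides
which imputation methods are valid, whether complete-case analyses are
biased, and where a study protocol can be fixed. This package implements a
two-step statistical screen that infers the mechanism from the missingness
pattern alone, for analysts working with long-format sensor exports.

## The method

A recording is a uniform-grid series with a boolean missing mask; a **gap**
is a maximal run of consecutive missing samples.

**Step 1 — gap-size distribution (MNAR screen).** If samples drop out as a
random (Poisson-like) process, gap sizes decline exponentially. Gap counts
are pooled over the cohort and fitted by maximum likelihood with the Planck
pmf (a normalised discrete exponential)

```
P(k; λ) = (1 − e^−λ) e^−λ(k−1),   k = 1, 2, …,   λ̂ = ln( k̄ / (k̄ − 1) )
```

with `k̄` the mean gap size. After truncating the table at the first gap size
with a count ≤ 5, a one-way chi-square test compares observed counts with the
fitted pmf (renormalised over the retained sizes). A significant departure
(p < 0.01) means the gaps are not produced by a random process: **MNAR**.
Thirteen alternative discrete families (geometric, Zipf/zeta, finite-support
Zipfian, Yule–Simon, Boltzmann, beta-binomial, …) are fitted the same way and
ranked by the sum of squared errors (SSE) between empirical and fitted
probabilities; a heavy-tailed winner diagnoses an excess of extreme gaps
typical of device-driven loss.

**Step 2 — dispersion over time (MAR screen).** Per subject, the percentage
of missing samples is computed in each time group — hour of day, weekday,
business vs weekend, measurement day — and compared across groups with the
Kruskal–Wallis test followed by Dunn's post hoc test with Bonferroni
correction. Any surviving pair means missingness depends on time: **MAR**;
otherwise **MCAR**. MNAR from Step 1 dominates the final verdict.

The simulator reproduces the causal device mechanisms behind such patterns:
an 8-hour CGM FIFO buffer flushed only by manual scans (no scans during
sleep ⇒ loss at the start of the night) and a tracker memory that fills after
about five days of dual-stream recording and stops recording steps until the
day-7 clinic visit clears it (⇒ measurement days 6–7 lost).

## Worked example

```python
from wearmiss import AnalysisConfig, preprocess_cohort, simulate_cohort
from wearmiss.cohort import analyze_modality
from wearmiss.simulate import scenario

cfg = AnalysisConfig()                      # every published threshold, as defaults
preset = scenario("mnar_zipf")              # heavy-tailed device gaps on HR
cohort = simulate_cohort(20, seed=7, modalities=("hr",), **preset)
recordings, log = preprocess_cohort(cohort.raw, cfg)
analysis = analyze_modality(recordings["hr"], cfg)
v = analysis.verdict
print(v.final, v.step1, v.step2, analysis.freq.total_gaps, v.planck_p)
```

Running `python examples/01_classify_mechanisms.py` (which does the above for
all three mechanism presets) prints:

```
scenario     truth  verdict  step1    step2    gaps  Planck p  loss %
mcar         MCAR   MCAR     M(C)AR   MCAR    36568     0.224    10.1
mar_night    MAR    MAR      M(C)AR   MAR     13709      0.86     3.5
mnar_zipf    MNAR   MNAR     MNAR     MCAR     1992         0     5.1
```

Reading: the uniform-dropout cohort's gap table is compatible with the Planck
fit (p = 0.22) and shows no time structure — MCAR. The night-weighted cohort
also passes Step 1 (p = 0.86) but Dunn flags night-vs-day hours — MAR. The
heavy-tailed cohort fails Step 1 outright (p ≈ 0) — MNAR. `loss %` is the
mean realised percent missing after preprocessing.

The other examples show the pmf ranking on contrasting gap regimes
(`02_gap_size_distributions.py`) and the two device-buffer dispersion
signatures — the 22:00–02:00 glucose night peak and the day-6/7 step loss
(`03_device_buffer_signatures.py`).

A thin CLI chains the pipeline stages over CSV/JSON files:

```bash
wearmiss simulate  --seed 3 --out sim --subjects 20 --scenario study
wearmiss preprocess --in sim --out pre
wearmiss analyze    --in pre --out report
wearmiss report     --in report --out summary
```

## Layout

- `src/wearmiss/simulate.py` — cohort generator, mechanism injectors, device
  and sleep models
- `src/wearmiss/preprocess.py` — CGM resampling + 18-min rule, zero-coding
  rules for HR/steps, wear-day and recording exclusions
- `src/wearmiss/gaps.py` — gap extraction, pooling/truncation, discrete-pmf
  registry, chi-square/SSE, Step-1 decision
- `src/wearmiss/dispersion.py` — time groupings, Kruskal–Wallis, Dunn,
  Step-2 decision
- `src/wearmiss/cohort.py` — final verdict, Spearman loss correlations,
  subgroup analyses, dispersion RMSE
- `src/wearmiss/io.py`, `cli.py`, `plots.py` — CSV/JSON schemas, pipeline
  CLI, report figures

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
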