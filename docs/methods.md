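# Methods

This note documents the statistical procedures, the synthetic-data models,
the parameter defaults and the numerical choices behind `wearmiss`, and what
the test suite does and does not establish about real data.

## 1. Problem setting

Input is long-format per-subject sensor data from a two-week free-living
protocol: continuous glucose (irregularly sampled, ~15-min median interval),
and 1/min heart-rate and step streams from a wrist tracker that emits the
value 0 for minutes without a measurement. The goal is to classify the
missing-data mechanism per modality:

- **MCAR** — missingness independent of time and of the unobserved values;
- **MAR** — missingness depends on observed structure (clock hour, weekday,
  measurement day) but not on the unobserved values;
- **MNAR** — missingness tied to the values themselves or to a non-random
  device process.

The classification is pattern-based: no covariate model is fitted, and the
verdict concerns the cohort-pooled pattern, not individuals.

## 2. Preprocessing rules

All thresholds live in `AnalysisConfig`, with the published rule set as
defaults.

**Glucose.** Raw samples are resampled to a 15-min grid anchored at the
first sample by linear interpolation. A grid point is *missing* when the
nearest raw sample on each side is more than 18 min away (`both_neighbors`,
the default). An alternative reading — any grid point strictly inside a raw
inter-sample interval longer than 19 min is missing (`long_interval`) — is a
config switch. The two differ for single dropped samples: a 30-min hole is
invisible to `both_neighbors` (every grid point is within 18 min of some
neighbour) but flagged by `long_interval`. Consequence: on the CGM grid,
sub-18-min holes are unobservable *by definition of the rule*, which is why
ground-truth recovery statements (Section 6) are made on the tracker
streams.

**Heart rate.** Zero values are missing; minutes absent from the export are
first filled as 0 (device convention). Negative values are rejected.

**Steps.** A minute is missing when both HR and steps are 0 (a zero step
count with the wearer's pulse present is an observed zero — standing still).
Additionally, any maximal run of zero-step minutes whose overlap with the
08:00–22:00 day window is at least 120 min is marked missing *in full*,
including out-of-window minutes. The overlap criterion (rather than mere
intersection with the window) keeps ordinary overnight rest — which often
touches 22:00 — out of the missing mask; a worn tracker essentially never
sees two daytime hours with literally zero steps.

**Wear days.** Per local calendar day: the day is non-wear when observed HR
covers less than 70% of its minutes, or when the observed day-window step
total is ≤ 1000 (pro-rated on partial first/last days). The step criterion
is only assessed when at least half of the day-window step minutes are
*observed*: a day whose steps are already classified missing (e.g. device
storage overflow) carries no wear information of its own and is adjudicated
by the HR criterion alone. Without this gate, device-loss days would be
silently discarded as non-wear and the overflow signal the framework exists
to detect would vanish. Non-wear days are excised from both tracker
recordings — they are removed from the denominators, not counted as missing.

**Recordings** with more than 50% missing (strict) are excluded; every
exclusion (day or recording) is logged with the rule that fired and its
trigger value.

## 3. Step 1 — gap-size distribution

Gaps are maximal missing runs (runs touching a recording end count). Counts
are pooled over the cohort and truncated at the first size whose count is
≤ 5 — that size and all larger ones are dropped, zero-count sizes below the
cutoff are retained with count 0 — because chi-square expectations are
unreliable at small counts.

The reference model is the Planck pmf, `P(k; λ) ∝ e^{−λk}` on k ≥ 1, the
discrete analogue of the exponential inter-event law of a Poisson process.
Its MLE has the closed form `λ̂ = ln(k̄/(k̄−1))`; all gaps of size one
(`k̄ = 1`) give a degenerate fit, flagged and classified "insufficient".

*Support convention.* Families with natural support {0, 1, …} (Planck,
Poisson, negative binomial, …) are fitted on the shifted sizes k − 1;
families whose support already starts at 1 (zipf, zipfian, logarithmic,
Yule–Simon, uniform) use k directly. Bounded-support families (zipfian,
Boltzmann, uniform, hypergeometric, beta-binomial) use N = max retained size
as the support bound and are fitted on the retained table (larger sizes are
outside their support); unbounded families use the full pre-truncation
counts. Skellam and the discrete Laplace, whose natural support is all
integers, are renormalised onto {0..N}; they are ranking candidates only, as
are all non-Planck families — the MNAR decision uses only the Planck fit.
"zipf" and "zeta" name the same infinite-support power law.

*Goodness of fit.* Expected counts renormalise the fitted pmf over the
retained sizes so observed and expected totals match. The statistic is the
one-way chi-square with dof = (#retained sizes) − 1; dof is *not* reduced
for the estimated parameter (matching the plain one-way test), which makes
the test conservative — the measured type-I rate at α = 0.01 is below 0.01
(`reduce_dof_for_params` switches to the reduced-dof variant). SSE compares
empirical and renormalised fitted probabilities on the retained table and
ranks the families. Decision: chi-square p < α (default 0.01, strict)
⇒ MNAR, else M(C)AR.

## 4. Step 2 — missing-data dispersion

For each grouping — hour of day (24), weekday (7), business vs weekend (2),
measurement day (rolling 24-h windows from the recording anchor; a
calendar-day mode is a config switch) — the per-subject percentage of
missing samples per group is computed. Subjects with no samples in a group
are *undefined* there (dropped pairwise), never zero-filled.

Kruskal–Wallis (tie-corrected, chi-square approximation with k − 1 dof) is
the omnibus; Dunn's test on the pooled ranks, two-sided normal p multiplied
by the number of pairs within the grouping (Bonferroni, clipped at 1), is
the post hoc. Both are implemented from the rank formulas; the test suite
cross-checks them against scipy and an independent reimplementation.
Decision: any surviving Dunn pair in any grouping ⇒ MAR, else MCAR — the
post hoc governs, not the omnibus. Bonferroni is applied within each
grouping (an across-groupings correction is a config option, off by
default). The parametric ANOVA+Tukey alternative is deliberately not used
for the verdict.

*Known limitation.* With many groups and few subjects per group the Dunn
normal approximation is evaluated in its far tail (276 hour-pairs at
per-pair α ≈ 3.6×10⁻⁵) where it is mildly anti-conservative — a property of
every standard Dunn implementation. On a 15-min grid with 50 subjects the
measured family-wise false-flag rate across all four groupings is ≈ 3%; on a
1/min grid it can reach ≈ 5–8%.

## 5. Final verdict and cohort analyses

MNAR from Step 1 dominates; otherwise Step 2 decides; "insufficient" gap
tables give an indeterminate verdict. Step 2 always runs — time structure is
informative even for MNAR streams.

Cross-modality loss is compared by Spearman rank correlation of per-subject
percent missing (undefined below 3 common subjects). Subgroup analyses bin
subjects by loss amount ([0,10), [10,20), ≥20 %), gender, age (<50, [50,60),
[60,70], >70 — the shared upper edge right-closed), BMI (<30 / ≥30), HbA1c
(≤53 / >53 mmol/mol), years since diagnosis ([0,10), [10,20), ≥20) and
medication flags; continuous covariates are compared by KW + Dunn,
dichotomous ones by contingency chi-square without continuity correction
(flagged unreliable if any expected cell < 1), with an additional Bonferroni
factor for the number of covariates screened. Subgroup gap tables are tested
against the pooled fit by a one-way chi-square over the subgroup's retained
sizes. Dispersion shapes are compared by the RMSE between median vectors
normalised to unit sum — a metric (nonnegative, symmetric, zero iff equal).

## 6. The synthetic cohort generator

The generator emulates the study conditions: 14-day recordings starting on a
Thursday morning (subjects enrolled at a clinic visit, per-subject start
offset up to 2 h), per-subject sleep schedules (onset 23:00 ± 0.5 h,
duration 8 ± 0.5 h, small nightly jitter), descriptives drawn within the
published cohort's ranges (~60% male, age ~64, BMI ~33, HbA1c ~58 mmol/mol,
oral/insulin/other medication at 90/56/39%; no covariate–missingness
coupling unless configured).

Signals are phenomenologically plausible but simple, because the analysis
consumes only missingness structure: glucose is a mean-reverting AR(1)
around 7.5 mmol/L clipped to 3.9–13; HR a circadian baseline (55–90 bpm)
plus noise, never 0 while measuring; steps are zero-inflated daytime
activity bouts whose genuine zero runs stay well under 2 h during the day
window, so the zero-run rule is exercised against true negatives. What the
values do **not** model: meals, insulin, exercise physiology, sensor drift —
so passing tests say nothing about value-level realism, only about
missingness structure.

Mechanism injectors (all return boolean missing masks; mechanisms compose by
union; everything is deterministic given the seed, via generators spawned
from one master):

- `mcar_iid` — iid sample dropout (run lengths geometric by construction);
- `mcar_gap_process` / `mnar_device` — iid gap starts with lengths from a
  named family (geometric / constant / Planck / Zipf), optionally plus
  excess single-sample gaps (the device-error signature);
- `mar_time` — hour-profile dropout (24 probabilities);
- `buffer` — device-storage loss. Two semantics: **FIFO** (a sample survives
  iff some sync s has s − capacity ≤ t ≤ s; closed interval, terminal sync
  appended at the recording end) models the flash CGM patch; **stop-when-
  full** (a sample is recorded iff less than capacity has elapsed since the
  last memory clear) models the tracker step channel, which stops rather
  than overwrites.

Device defaults: CGM 8-h buffer, scan-event sync at 0.5 scans per waking
hour (a Poisson stream restricted to waking intervals — the cohort's true
scan frequency is unknown, so this is a free parameter, not an estimate);
tracker 5.0-day effective capacity with a scheduled day-7 visit sync. The
5-day figure encodes "the memory fills during day 6 of dual-stream
recording": it reproduces both observed signatures at once — total step loss
on measurement days 6–7 until the day-7 sync, and step recordings ending
near day 12 when the memory fills again before the final visit — whereas a
capacity of a full 6 days would lose day 7 only. The nominal (marketing)
capacity is larger; the effective figure is what the loss pattern implies.

Glucose missingness operates on the raw irregular samples and missing
samples are dropped from the emitted stream; HR/steps missingness is
zero-coded in place, except the stop-when-full tracker, which emits nothing
at all while full. Ground-truth masks are stream-native. Recovery guarantee:
on the tracker streams preprocessing reproduces injected masks exactly (HR)
or to ≥ 99% per-sample agreement (steps under overflow; the maximal-run rule
attaches adjacent genuine zero minutes). On the CGM grid no per-sample
guarantee is possible (Section 2); there, recovered gap-size *distributions*
are the meaningful target: an iid raw dropout of rate r reappears on the
grid as the geometric law of runs ≥ 2, shifted by one.

### Scenario presets and their calibration

`scenario(name)` bundles the study conditions: `mcar` (iid 0.10),
`mar_night` (hour profile 0.06 at 22:00–02:00 / 0.03 otherwise), `mnar_zipf`
(gap starts 0.005, sizes Zipf a = 2), `cgm_buffer`, `tracker_overflow`
(tracker overflow plus the device's sporadic single-minute HR read errors at
2%), and `study` (all device mechanisms together).

The `mar_night` contrast was set by a design-time power/level analysis, not
by the detection threshold alone: MAR dropout with two very different hourly
rates pools a *mixture* of two geometric gap laws, which with tens of
thousands of gaps is itself detectably non-exponential — Step 1 would then
(statistically correctly) report the time-varying process as MNAR. A 2:1
night/day contrast keeps the pooled law within the exponential family's
neighbourhood while giving the dispersion step essentially unbounded power.
This is a genuine boundary of the framework, not of the implementation: the
Step-1/Step-2 division assumes the time dependence is mild enough that the
pooled gap-size law stays near-exponential. The same applies to the CGM
buffer mechanism: its nightly lost interval is a sum of two scan waiting
times (Gamma-like, hump-shaped), so with enough pooled gaps Step 1 detects
the device process itself and reports MNAR — defensible on the glossary's
own terms (a non-random device process), while at low pooled gap counts
(~100) the chi-square lacks power and such cohorts read as M(C)AR + night
MAR.

## 7. Numerical choices

- Timestamps are timezone-naive wall-clock `datetime64[s]`; groupings use
  local clock arithmetic (epoch day 0 is a Thursday, so weekday is modular
  arithmetic on the day index).
- Optimisation: 1-parameter families use bounded Brent on the multinomial
  negative log-likelihood; 2-parameter families Nelder–Mead on
  log-transformed parameters; the hypergeometric uses a coarse integer grid.
  Non-converged fits are flagged and excluded from the ranking.
- Expected chi-square counts are floored at 1e-300, so a fitted pmf with no
  mass on an observed size yields an (honest) infinite statistic rather than
  a division warning.
- Ties in the rank tests use the standard corrections
  (`Σ(t³−t)/(N³−N)` for KW, `Σ(t³−t)/(12(N−1))` in the Dunn variance).
  All-identical data return H = 0, p = 1 by convention.
- Boundary conventions, all strict/documented: missing-fraction exclusion at
  > 0.50; MNAR at p < α; loss bins left-closed; age upper edge right-closed;
  a sample at the exact sync instant is recorded.
- Reports serialise reals via JSON `repr` round-tripping (bit-stable on
  re-write); integers exactly.

## 8. Problem sizes in tests

The acceptance suite runs cohorts of 50 subjects × 14 days (the generator's
default study size): 100 seeds per mechanism for recovery (each a full
simulate-preprocess-classify cycle), 1000 replicates of 500-gap tables for
the Step-1 type-I rate, and 200 iid-dropout cohorts on the 15-min grid for
the Step-2 family-wise rate. `scripts/acceptance.py` reports the same
quantities at 30/300/100 replicates. These sizes give Monte-Carlo standard
errors comfortably inside the asserted margins (e.g. ±3.5 points on a 90%
recovery rate at 100 seeds).

## 9. Known limitations

- Steps-only dropout shorter than the 2-h run threshold with HR present is
  *undetectable by construction* of the published rules — indistinguishable
  from sitting still. The simulator can inject it; preprocessing will not
  see it.
- The Dunn far-tail anti-conservatism (Section 4) slightly inflates MAR
  verdicts on very fine grids with many groups.
- Truncation at count ≤ 5 discards the extreme tail precisely where MNAR
  mechanisms live; heavy-tailed mechanisms are still detected through the
  excess of small gaps, but a mechanism manifesting *only* in rare huge gaps
  can evade Step 1.
- Verdicts are cohort-level; per-subject heterogeneity (some subjects MCAR,
  others MNAR) is averaged out by pooling.
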