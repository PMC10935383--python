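"""Synthetic cohorts with known ground-truth missingness mechanisms.

The generator emulates a two-week free-living recording in adults with type 2
diabetes: a flash glucose monitor sampled irregularly around a 15-min median
interval whose on-sensor FIFO buffer holds 8 h and is flushed only by manual
scans, and a wrist tracker producing 1/min heart-rate and step streams that
zero-code absent minutes and whose on-device storage fills after a few days
unless synchronised at a clinic visit.

Missingness is *injected* by explicit mechanism models, and the injected mask
is returned alongside the data, so every downstream classification stage can
be validated against a known mechanism label.

Signal values are phenomenologically plausible but deliberately simple (the
analysis consumes only missingness structure); step values do include genuine
zero runs so the zero-run preprocessing rules are exercised against true
negatives.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.signal import lfilter

from .core import MINUTE, GroundTruth, RawSeries, as_datetime64, hour_of_day

__all__ = [
    "DeviceModel",
    "SleepModel",
    "MechanismSpec",
    "CohortData",
    "cgm_device",
    "tracker_device",
    "inject_iid_dropout",
    "inject_gap_process",
    "inject_time_dependent_dropout",
    "inject_buffer_loss",
    "inject_overflow_stop",
    "simulate_scan_times",
    "simulate_cohort",
    "scenario",
]

MECHANISM_KINDS = ("mcar_iid", "mcar_gap_process", "mar_time", "mnar_device", "buffer")

#: simulated study start: a Thursday morning (subjects enrolled on Thursdays)
DEFAULT_START = np.datetime64("2019-03-07T09:00:00")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# device / behaviour models
# ---------------------------------------------------------------------------


@dataclass
class DeviceModel:
    """On-device storage and synchronisation behaviour.

    ``overflow='fifo'`` drops the *oldest* stored samples when capacity is
    exceeded (flash CGM patch); ``overflow='stop'`` stops recording until the
    next synchronisation clears the memory (activity-tracker step channel).
    """

    buffer_capacity_hours: float
    sync_policy: str = "scan_events"  # or "scheduled_visits"
    scan_rate_per_hour: float = 0.5  # mean manual scans per waking hour
    visit_days: tuple[float, ...] = (7.0,)  # days after start, for scheduled sync
    overflow: str = "fifo"  # or "stop"

    def __post_init__(self) -> None:
        if self.buffer_capacity_hours <= 0:
            raise ValueError("buffer_capacity must be positive")
        if self.scan_rate_per_hour < 0:
            raise ValueError("scan_rate must be >= 0")
        if self.sync_policy not in ("scan_events", "scheduled_visits"):
            raise ValueError("sync_policy must be scan_events|scheduled_visits")
        if self.overflow not in ("fifo", "stop"):
            raise ValueError("overflow must be fifo|stop")


def cgm_device() -> DeviceModel:
    """Flash glucose monitor: 8-h FIFO buffer flushed by manual scans."""
    return DeviceModel(8.0, "scan_events", scan_rate_per_hour=0.5)


def tracker_device() -> DeviceModel:
    """Activity tracker: storage effectively full after ~5 days of dual-stream
    recording (nominally more), cleared at a scheduled day-7 clinic visit, and
    the step channel stops recording while full."""
    return DeviceModel(5.0 * 24.0, "scheduled_visits", visit_days=(7.0,), overflow="stop")


@dataclass
class SleepModel:
    """Per-subject sleep schedule: onset clock time and duration, with
    between-subject jitter (and a small within-subject nightly jitter)."""

    onset_hour: float = 23.0
    onset_jitter_hours: float = 0.5
    duration_hours: float = 8.0
    duration_jitter_hours: float = 0.5
    nightly_jitter_hours: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.duration_hours < 24.0:
            raise ValueError("sleep duration must be in (0, 24) hours")

    def sample_subject(self, rng: np.random.Generator) -> tuple[float, float]:
        onset = self.onset_hour + rng.normal(0.0, self.onset_jitter_hours)
        duration = float(
            np.clip(
                self.duration_hours + rng.normal(0.0, self.duration_jitter_hours),
                1.0,
                23.0,
            )
        )
        return float(onset), duration


@dataclass
class MechanismSpec:
    """Declarative description of one injected missingness mechanism."""

    kind: str
    rate: float = 0.0  # mcar_iid sample dropout probability
    gap_start_rate: float = 0.0  # per-sample gap start probability
    gap_size_family: tuple = ("geometric", 0.5)  # name + params, support >= 1
    hour_profile: tuple | None = None  # 24 dropout probabilities (mar_time)
    excess_single_gap_prob: float = 0.0  # extra iid singles (mnar_device)

    def __post_init__(self) -> None:
        if self.kind not in MECHANISM_KINDS:
            raise ValueError(
                f"unsupported mechanism kind {self.kind!r}; expected one of {MECHANISM_KINDS}"
            )
        for p in (self.rate, self.gap_start_rate, self.excess_single_gap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.hour_profile is not None:
            prof = np.asarray(self.hour_profile, dtype=float)
            if prof.shape != (24,):
                raise ValueError("hour_profile must have length 24")
            if np.any((prof < 0) | (prof > 1)):
                raise ValueError("hour_profile entries must lie in [0, 1]")
            self.hour_profile = tuple(prof)


# ---------------------------------------------------------------------------
# mask injectors
# ---------------------------------------------------------------------------


def inject_iid_dropout(grid_length: int, rate: float, seed) -> np.ndarray:
    """Each sample missing independently with probability ``rate``.

    Consecutive-missing run lengths are then geometric with success
    probability ``1 - rate``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    rng = _rng(seed)
    return rng.random(int(grid_length)) < rate


def sample_gap_sizes(gap_size_family, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` gap lengths (integers >= 1) from a named discrete family."""
    name, *params = gap_size_family
    if name == "constant":
        (k,) = params
        if k < 1:
            raise ValueError("gap size must be >= 1")
        return np.full(n, int(k), dtype=np.int64)
    if name == "geometric":
        (p,) = params
        return rng.geometric(p, size=n).astype(np.int64)
    if name == "zipf":
        (a,) = params
        return scipy.stats.zipf.rvs(a, size=n, random_state=rng).astype(np.int64)
    if name == "planck":
        (lam,) = params
        return (scipy.stats.planck.rvs(lam, size=n, random_state=rng) + 1).astype(np.int64)
    raise ValueError(f"unknown gap size family {name!r}")


def _mask_from_gaps(grid_length: int, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    delta = np.zeros(grid_length + 1, dtype=np.int64)
    ends = np.minimum(starts + sizes, grid_length)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    return np.cumsum(delta[:-1]) > 0


def inject_gap_process(
    grid_length: int,
    gap_start_rate: float,
    gap_size_family,
    seed,
    forced_starts=None,
) -> np.ndarray:
    """Gaps start iid per sample; each gap's length is drawn from the family;
    overlapping gaps merge (union)."""
    if not 0.0 <= gap_start_rate <= 1.0:
        raise ValueError("gap_start_rate must lie in [0, 1]")
    rng = _rng(seed)
    n = int(grid_length)
    starts = np.flatnonzero(rng.random(n) < gap_start_rate)
    if forced_starts is not None:
        starts = np.unique(np.concatenate([starts, np.asarray(forced_starts, dtype=np.int64)]))
    if starts.size == 0:
        return np.zeros(n, dtype=bool)
    sizes = sample_gap_sizes(gap_size_family, starts.size, rng)
    return _mask_from_gaps(n, starts, sizes)


def inject_time_dependent_dropout(times, hour_profile, seed) -> np.ndarray:
    """Sample at clock hour ``h`` missing independently with
    probability ``hour_profile[h]``."""
    prof = np.asarray(hour_profile, dtype=float)
    if prof.shape != (24,):
        raise ValueError("hour_profile must have length 24")
    if np.any((prof < 0) | (prof > 1)):
        raise ValueError("hour_profile entries must lie in [0, 1]")
    times = np.asarray(times)
    if np.issubdtype(times.dtype, np.datetime64):
        hours = hour_of_day(times)
    else:
        hours = times.astype(np.int64) % 24
    rng = _rng(seed)
    return rng.random(hours.size) < prof[hours]


def _times_to_hours(times) -> np.ndarray:
    times = np.asarray(times)
    if np.issubdtype(times.dtype, np.datetime64):
        t0 = times.astype("datetime64[s]").astype(np.int64)
        return (t0 - t0[0]) / 3600.0 if t0.size else t0.astype(float)
    return times.astype(float)


def inject_buffer_loss(times, buffer_capacity_hours: float, sync_times) -> np.ndarray:
    """FIFO-buffer data loss: a sample at time ``t`` survives iff some
    synchronisation ``s`` exists with ``s - capacity <= t <= s``.

    A terminal sync at the recording end is appended automatically (the device
    is read out when returned). Returns the *missing* mask.
    """
    t = _times_to_hours(times)
    if t.size == 0:
        raise ValueError("empty timestamps")
    syncs = np.asarray(_times_to_hours_rel(sync_times, times), dtype=float)
    if syncs.size and np.any(np.diff(syncs) < 0):
        raise ValueError("sync_times must be sorted")
    syncs = np.append(syncs, t[-1])  # terminal sync at recording end
    idx = np.searchsorted(syncs, t, side="left")
    idx = np.minimum(idx, syncs.size - 1)
    observed = (syncs[idx] - t) <= buffer_capacity_hours
    return ~observed


def inject_overflow_stop(times, buffer_capacity_hours: float, sync_times) -> np.ndarray:
    """Stop-when-full data loss: the device records a sample at ``t`` iff less
    than ``capacity`` has elapsed since the last memory clear (recording start
    or any synchronisation). Returns the *missing* mask."""
    t = _times_to_hours(times)
    if t.size == 0:
        raise ValueError("empty timestamps")
    syncs = np.asarray(_times_to_hours_rel(sync_times, times), dtype=float)
    clears = np.concatenate([[t[0]], syncs])
    clears = np.sort(clears)
    idx = np.searchsorted(clears, t, side="right") - 1
    idx = np.maximum(idx, 0)
    recorded = (t - clears[idx]) <= buffer_capacity_hours
    return ~recorded


def _times_to_hours_rel(sync_times, ref_times) -> np.ndarray:
    """Sync times on the same hours-from-recording-start axis as the samples."""
    sync_times = np.asarray(sync_times)
    if sync_times.size == 0:
        return sync_times.astype(float)
    if np.issubdtype(sync_times.dtype, np.datetime64):
        ref = np.asarray(ref_times).astype("datetime64[s]").astype(np.int64)[0]
        return (sync_times.astype("datetime64[s]").astype(np.int64) - ref) / 3600.0
    return sync_times.astype(float)


def simulate_scan_times(
    sleep: SleepModel, scan_rate_per_hour: float, days: float, seed,
    wake_intervals=None,
) -> np.ndarray:
    """Poisson stream of manual scan events restricted to waking intervals.

    Returns event times in hours from recording start, sorted. If
    ``wake_intervals`` (list of ``(start, end)`` hour pairs) is given it
    overrides the schedule drawn from ``sleep``.
    """
    if scan_rate_per_hour < 0:
        raise ValueError("scan_rate must be >= 0")
    rng = _rng(seed)
    if wake_intervals is None:
        onset, duration = sleep.sample_subject(rng)
        wake_intervals = _wake_intervals(onset, duration, days, 0.0, sleep, rng)
    events = []
    for lo, hi in wake_intervals:
        if hi <= lo:
            continue
        n = rng.poisson(scan_rate_per_hour * (hi - lo))
        if n:
            events.append(rng.uniform(lo, hi, size=n))
    if not events:
        return np.empty(0, dtype=float)
    return np.sort(np.concatenate(events))


def _wake_intervals(onset_hour, duration, days, start_hour, sleep, rng):
    """Waking intervals in hours from recording start.

    ``start_hour`` is the clock hour of the recording start; night ``d`` begins
    at clock time ``onset_hour`` of day ``d`` (possibly past midnight).
    """
    total = days * 24.0
    intervals = []
    cursor = 0.0
    n_nights = int(np.ceil(days)) + 1
    for d in range(-1, n_nights):
        jitter = rng.normal(0.0, sleep.nightly_jitter_hours, size=2)
        s = d * 24.0 + (onset_hour + jitter[0]) - start_hour
        e = s + duration + jitter[1]
        if e <= 0 or s >= total:
            continue
        s, e = max(s, 0.0), min(e, total)
        if s > cursor:
            intervals.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < total:
        intervals.append((cursor, total))
    return intervals


def _sleep_mask(hours_from_start: np.ndarray, wake_intervals, total) -> np.ndarray:
    asleep = np.ones(hours_from_start.size, dtype=bool)
    for lo, hi in wake_intervals:
        asleep &= ~((hours_from_start >= lo) & (hours_from_start < hi))
    return asleep


# ---------------------------------------------------------------------------
# signal models
# ---------------------------------------------------------------------------


def _glucose_values(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth mean-reverting (AR(1)) glucose trace in ~4-12 mmol/L."""
    eps = rng.normal(0.0, 0.25, size=n)
    dev = lfilter([1.0], [1.0, -0.95], eps)
    return np.clip(7.5 + dev, 3.9, 13.0)


def _hr_values(clock_hours: np.ndarray, asleep: np.ndarray, rng) -> np.ndarray:
    base = 70.0 + 8.0 * np.sin(2.0 * np.pi * (clock_hours - 15.0) / 24.0)
    base = np.where(asleep, 57.0, base)
    return np.clip(np.round(base + rng.normal(0.0, 4.0, clock_hours.size)), 35, 200)


def _steps_values(clock_hours: np.ndarray, asleep: np.ndarray, rng) -> np.ndarray:
    """Zero-inflated daytime activity: short walking bouts, genuine zero runs
    between them (typically well under 2 h)."""
    p_walk = np.where((clock_hours >= 8) & (clock_hours < 21), 0.12, 0.04)
    p_walk = np.where(asleep, 0.0, p_walk)
    walking = rng.random(clock_hours.size) < p_walk
    return np.where(walking, rng.poisson(75.0, clock_hours.size), 0).astype(float)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """Simulated cohort: raw device streams, injected-missingness oracle and a
    descriptives table."""

    raw: list
    truth: list
    descriptives: pd.DataFrame
    mechanism_labels: dict

    def raw_by_subject(self):
        out: dict = {}
        for rs in self.raw:
            out.setdefault(rs.subject_id, {})[rs.modality] = rs
        return out


def _descriptives(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates drawn within the published cohort's ranges (type 2 diabetes
    outpatients): ~60% male, median age ~64, BMI ~33, HbA1c ~58 mmol/mol."""
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n_subjects)],
            "gender": np.where(rng.random(n_subjects) < 0.60, "male", "female"),
            "age_years": np.clip(np.round(rng.normal(63, 9, n_subjects)), 30, 90),
            "bmi": np.round(np.clip(rng.normal(33, 4.5, n_subjects), 18, 50), 1),
            "hba1c_mmol_mol": np.round(np.clip(rng.normal(58, 8, n_subjects), 35, 100), 0),
            "years_since_diagnosis": np.round(
                np.clip(rng.normal(14, 8, n_subjects), 0, 40), 0
            ),
            "med_oral": (rng.random(n_subjects) < 0.90).astype(int),
            "med_insulin": (rng.random(n_subjects) < 0.56).astype(int),
            "med_other": (rng.random(n_subjects) < 0.39).astype(int),
        }
    )


def _mechanism_mask(
    mech: MechanismSpec | None,
    hours_abs: np.ndarray,
    clock_hours: np.ndarray,
    rng: np.random.Generator,
    device: DeviceModel | None,
    wake_intervals,
    start_hour: float,
) -> np.ndarray:
    n = hours_abs.size
    if mech is None:
        return np.zeros(n, dtype=bool)
    if mech.kind == "mcar_iid":
        return inject_iid_dropout(n, mech.rate, rng)
    if mech.kind == "mcar_gap_process":
        return inject_gap_process(n, mech.gap_start_rate, mech.gap_size_family, rng)
    if mech.kind == "mar_time":
        return inject_time_dependent_dropout(clock_hours, mech.hour_profile, rng)
    if mech.kind == "mnar_device":
        mask = inject_gap_process(n, mech.gap_start_rate, mech.gap_size_family, rng)
        if mech.excess_single_gap_prob > 0:
            mask |= inject_iid_dropout(n, mech.excess_single_gap_prob, rng)
        return mask
    if mech.kind == "buffer":
        if device is None:
            raise ValueError("buffer mechanism requires a DeviceModel")
        if device.sync_policy == "scan_events":
            syncs = simulate_scan_times(
                SleepModel(), device.scan_rate_per_hour, 0.0, rng,
                wake_intervals=wake_intervals,
            )
        else:
            syncs = np.asarray(device.visit_days, dtype=float) * 24.0
        rel_hours = hours_abs - hours_abs[0]
        if device.overflow == "fifo":
            return inject_buffer_loss(rel_hours, device.buffer_capacity_hours, syncs)
        return inject_overflow_stop(rel_hours, device.buffer_capacity_hours, syncs)
    raise ValueError(f"unsupported mechanism kind {mech.kind!r}")


def simulate_cohort(
    n_subjects: int,
    days: float = 14.0,
    mechanisms: dict | None = None,
    devices: dict | None = None,
    sleep: SleepModel | None = None,
    seed=0,
    modalities=("glucose", "hr", "steps"),
    start=DEFAULT_START,
) -> CohortData:
    """Simulate ``n_subjects`` recordings of ``days`` days.

    ``mechanisms`` maps modality -> :class:`MechanismSpec` (or ``None``);
    ``devices`` maps modality -> :class:`DeviceModel` for buffer mechanisms.
    Glucose is sampled irregularly around a 15-min median interval and missing
    raw samples are *dropped* from the emitted stream; HR/steps are 1/min and
    missing minutes are emitted as value 0 (device convention), except that
    the step channel of a stop-when-full tracker emits nothing at all while
    the device memory is full.

    Deterministic given ``seed``: identical inputs give bit-identical output.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    mechanisms = dict(mechanisms or {})
    devices = dict(devices or {})
    sleep = sleep or SleepModel()
    root = _rng(seed)
    desc = _descriptives(n_subjects, root)
    child_rngs = root.spawn(n_subjects)

    start = np.datetime64(start, "s")
    start_midnight = start.astype("datetime64[D]").astype("datetime64[s]")
    raw: list[RawSeries] = []
    truth: list[GroundTruth] = []
    labels = {
        m: (mechanisms.get(m).kind if mechanisms.get(m) is not None else "none")
        for m in modalities
    }

    n_minutes = int(round(days * 1440))
    for i in range(n_subjects):
        rng = child_rngs[i]
        sid = f"S{i:03d}"
        offset_min = int(rng.integers(0, 120))
        t0 = start + offset_min * MINUTE
        start_hour = (t0 - start_midnight).astype("timedelta64[s]").astype(float) / 3600.0
        start_hour = start_hour % 24.0
        onset, duration = sleep.sample_subject(rng)
        wake = _wake_intervals(onset, duration, days, start_hour, sleep, rng)

        if "glucose" in modalities:
            ivals = np.clip(rng.normal(15.0, 1.3, size=n_minutes // 10), 10.0, 25.0)
            t_min = np.cumsum(ivals)
            t_min = np.concatenate([[0.0], t_min[t_min <= days * 1440.0]])
            g_hours = t_min / 60.0
            g_clock = (start_hour + g_hours) % 24.0
            g_times = t0 + np.round(t_min * 60.0).astype(np.int64).astype("timedelta64[s]")
            g_vals = _glucose_values(g_times.size, rng)
            g_mask = _mechanism_mask(
                mechanisms.get("glucose"), g_hours, g_clock, rng,
                devices.get("glucose"), wake, start_hour,
            )
            keep = ~g_mask
            raw.append(RawSeries(sid, "glucose", g_times[keep], g_vals[keep]))
            truth.append(GroundTruth(sid, "glucose", g_times, g_mask, labels["glucose"]))

        if "hr" in modalities or "steps" in modalities:
            m_hours = np.arange(n_minutes) / 60.0
            m_clock = (start_hour + m_hours) % 24.0
            m_times = t0 + (np.arange(n_minutes) * 60).astype("timedelta64[s]")
            asleep = _sleep_mask(m_hours, wake, days * 24.0)

        if "hr" in modalities:
            hr_vals = _hr_values(m_clock, asleep, rng)
            hr_mask = _mechanism_mask(
                mechanisms.get("hr"), m_hours, m_clock, rng,
                devices.get("hr"), wake, start_hour,
            )
            raw.append(RawSeries(sid, "hr", m_times, np.where(hr_mask, 0.0, hr_vals)))
            truth.append(GroundTruth(sid, "hr", m_times, hr_mask, labels["hr"]))

        if "steps" in modalities:
            st_vals = _steps_values(m_clock, asleep, rng)
            st_mech = mechanisms.get("steps")
            st_dev = devices.get("steps")
            st_mask = _mechanism_mask(st_mech, m_hours, m_clock, rng, st_dev, wake, start_hour)
            stop_mode = (
                st_mech is not None
                and st_mech.kind == "buffer"
                and st_dev is not None
                and st_dev.overflow == "stop"
            )
            if stop_mode:
                # device memory full: nothing is recorded at all
                keep = ~st_mask
                raw.append(RawSeries(sid, "steps", m_times[keep], st_vals[keep]))
            else:
                raw.append(
                    RawSeries(sid, "steps", m_times, np.where(st_mask, 0.0, st_vals))
                )
            truth.append(GroundTruth(sid, "steps", m_times, st_mask, labels["steps"]))

    return CohortData(raw=raw, truth=truth, descriptives=desc, mechanism_labels=labels)


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

NIGHT_HOURS = (22, 23, 0, 1)


def night_profile(night_rate: float = 0.15, day_rate: float = 0.03,
                  night_hours=NIGHT_HOURS) -> tuple:
    prof = np.full(24, day_rate)
    prof[list(night_hours)] = night_rate
    return tuple(prof)


def scenario(name: str, modality: str = "hr") -> dict:
    """Preset mechanism/device bundles for the study conditions.

    Returns a dict with ``mechanisms`` and ``devices`` keyword arguments for
    :func:`simulate_cohort`. The single-mechanism presets (``mcar``,
    ``mar_night``, ``mnar_zipf``) inject into ``modality`` (default the HR
    stream, whose 1/min zero-coded grid preserves the injected mask exactly
    through preprocessing).
    """
    if name == "clean":
        return {"mechanisms": {}, "devices": {}}
    if name == "mcar":
        return {
            "mechanisms": {modality: MechanismSpec("mcar_iid", rate=0.10)},
            "devices": {},
        }
    if name == "mar_night":
        # time-dependent but otherwise random dropout; the night/day contrast
        # keeps the pooled gap-size law near-exponential (the MAR regime this
        # screen is built for) while the hour dispersion is strongly flagged
        return {
            "mechanisms": {
                modality: MechanismSpec(
                    "mar_time", hour_profile=night_profile(0.06, 0.03)
                )
            },
            "devices": {},
        }
    if name == "mnar_zipf":
        return {
            "mechanisms": {
                modality: MechanismSpec(
                    "mnar_device", gap_start_rate=0.005, gap_size_family=("zipf", 2.0)
                )
            },
            "devices": {},
        }
    if name == "cgm_buffer":
        return {
            "mechanisms": {"glucose": MechanismSpec("buffer")},
            "devices": {"glucose": cgm_device()},
        }
    if name == "tracker_overflow":
        return {
            "mechanisms": {
                "steps": MechanismSpec("buffer"),
                "hr": MechanismSpec("mnar_device", gap_start_rate=0.0,
                                     excess_single_gap_prob=0.02),
            },
            "devices": {"steps": tracker_device()},
        }
    if name == "study":
        # all three device mechanisms at once, as in the emulated protocol
        return {
            "mechanisms": {
                "glucose": MechanismSpec("buffer"),
                "hr": MechanismSpec(
                    "mnar_device", gap_start_rate=0.002,
                    gap_size_family=("geometric", 0.25),
                    excess_single_gap_prob=0.02,
                ),
                "steps": MechanismSpec("buffer"),
            },
            "devices": {"glucose": cgm_device(), "steps": tracker_device()},
        }
    raise ValueError(f"unknown scenario {name!r}")
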