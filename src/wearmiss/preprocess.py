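"""Raw streams -> uniform-grid recordings with explicit missing masks.

Modality-specific missingness definitions:

* glucose — irregular raw samples are resampled to a 15-min grid by linear
  interpolation; a grid point is missing when the nearest raw sample on each
  side is more than 18 min away (``both_neighbors`` rule; a ``long_interval``
  variant marks every grid point inside a raw inter-sample interval longer
  than 19 min instead).
* heart rate — the tracker zero-codes unmeasured minutes, so value 0 is
  missing by definition; minutes absent from the export are filled as 0 first.
* steps — a minute is missing when both HR and steps are 0 (can't distinguish
  device-off from standing still otherwise), and any maximal zero-step run
  with at least 2 h of overlap with the 08:00-22:00 day window is treated as
  missing in full (a worn tracker essentially never sees 2+ daytime hours
  with literally zero steps).

Day-level wear criteria then remove non-wear days entirely (they are excised,
not counted as missing), and recordings losing more than half their samples
are excluded.
"""
from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .core import (
    DAY,
    MINUTE,
    ExclusionLog,
    RawSeries,
    Recording,
    day_index,
    hour_of_day,
)

__all__ = [
    "resample_glucose",
    "define_hr_missing",
    "define_steps_missing",
    "filter_wear_days",
    "exclude_recordings",
    "preprocess_cohort",
]


# ---------------------------------------------------------------------------
# glucose
# ---------------------------------------------------------------------------


def resample_glucose(raw: RawSeries, cfg: AnalysisConfig | None = None) -> Recording:
    """Resample an irregular CGM stream to a uniform grid anchored at the
    first raw sample, with the distance-based missingness rule."""
    cfg = cfg or AnalysisConfig()
    if raw.modality != "glucose":
        raise ValueError("resample_glucose expects a glucose series")
    if raw.n < 2:
        raise ValueError("need at least 2 raw samples to resample")
    step_s = cfg.grid_minutes * 60.0
    t = raw.times.astype(np.int64).astype(float)  # seconds
    n_grid = int((t[-1] - t[0]) // step_s) + 1
    grid = t[0] + np.arange(n_grid) * step_s
    values = np.interp(grid, t, raw.values)

    # nearest raw sample at or before / at or after each grid point
    right = np.searchsorted(t, grid, side="right")
    prev_gap = grid - t[np.clip(right - 1, 0, t.size - 1)]
    left = np.searchsorted(t, grid, side="left")
    next_gap = t[np.clip(left, 0, t.size - 1)] - grid
    thresh = cfg.missing_threshold_minutes * 60.0
    if cfg.cgm_missing_rule == "both_neighbors":
        missing = (prev_gap > thresh) & (next_gap > thresh)
    else:  # long_interval: inside an inter-sample interval > 19 min
        on_sample = (prev_gap == 0) | (next_gap == 0)
        interval = prev_gap + next_gap
        missing = ~on_sample & (interval > cfg.long_interval_minutes * 60.0)

    times = raw.times[0] + (np.arange(n_grid) * step_s).astype(np.int64).astype(
        "timedelta64[s]"
    )
    return Recording(
        raw.subject_id,
        "glucose",
        times,
        values,
        missing,
        np.timedelta64(int(step_s), "s"),
    )


# ---------------------------------------------------------------------------
# tracker streams
# ---------------------------------------------------------------------------


def _minute_grid(raw: RawSeries) -> tuple[np.ndarray, np.ndarray]:
    """1/min grid spanning the raw series; absent minutes filled with 0
    (the device convention for 'no measurement')."""
    t0 = raw.times[0].astype("datetime64[m]").astype("datetime64[s]")
    t1 = raw.times[-1].astype("datetime64[m]").astype("datetime64[s]")
    n = int((t1 - t0) / MINUTE) + 1
    times = t0 + (np.arange(n) * 60).astype("timedelta64[s]")
    values = np.zeros(n, dtype=float)
    idx = ((raw.times - t0) / MINUTE).astype(np.int64)
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate minutes in raw series")
    values[idx] = raw.values
    return times, values


def define_hr_missing(raw: RawSeries) -> Recording:
    """HR on a 1/min grid; zero values (and absent minutes) are missing."""
    if raw.modality != "hr":
        raise ValueError("define_hr_missing expects an hr series")
    if np.any(raw.values < 0):
        raise ValueError("negative heart rate")
    times, values = _minute_grid(raw)
    missing = values == 0.0
    return Recording(raw.subject_id, "hr", times, values, missing, MINUTE)


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, end) half-open index pairs."""
    if is_zero.size == 0:
        return []
    z = is_zero.astype(np.int8)
    d = np.diff(np.concatenate([[0], z, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def define_steps_missing(
    steps_raw: RawSeries, hr_rec: Recording, cfg: AnalysisConfig | None = None
) -> Recording:
    """Step stream on the HR minute grid with the combined missingness rules.

    The step grid is the overlap of the two streams' spans; grids offset by a
    non-integer number of minutes are rejected.
    """
    cfg = cfg or AnalysisConfig()
    if steps_raw.modality != "steps":
        raise ValueError("define_steps_missing expects a steps series")
    if hr_rec.grid_step != MINUTE:
        raise ValueError("hr recording must be on a 1/min grid")
    times, values = _minute_grid(steps_raw)

    # crop both to the common span
    lo = max(times[0], hr_rec.times[0])
    hi = min(times[-1], hr_rec.times[-1])
    if hi < lo:
        raise ValueError("steps and hr spans do not overlap")
    if ((lo - times[0]) % MINUTE != np.timedelta64(0, "s")) or (
        (lo - hr_rec.times[0]) % MINUTE != np.timedelta64(0, "s")
    ):
        raise ValueError("steps grid is not minute-aligned with hr grid")
    s_sel = (times >= lo) & (times <= hi)
    times, values = times[s_sel], values[s_sel]
    h_sel = (hr_rec.times >= lo) & (hr_rec.times <= hi)
    hr_missing = hr_rec.missing[h_sel]
    if hr_missing.size != times.size:
        raise ValueError("hr grid does not align with steps grid")

    zero = values == 0.0
    missing = zero & hr_missing

    # zero-step runs with >= `zero_step_run_minutes` of overlap with the
    # day window are missing in full (including out-of-window minutes)
    hours = hour_of_day(times)
    in_window = (hours >= cfg.day_window[0]) & (hours < cfg.day_window[1])
    for start, end in _zero_runs(zero):
        if end - start < cfg.zero_step_run_minutes:
            continue
        if int(in_window[start:end].sum()) >= cfg.zero_step_run_minutes:
            missing[start:end] = True

    return Recording(steps_raw.subject_id, "steps", times, values, missing, MINUTE)


# ---------------------------------------------------------------------------
# day- and recording-level exclusions
# ---------------------------------------------------------------------------


def filter_wear_days(
    hr_rec: Recording, steps_rec: Recording, cfg: AnalysisConfig | None = None
) -> tuple[Recording, Recording, ExclusionLog]:
    """Remove non-wear calendar days from both tracker recordings.

    A day is non-wear when observed HR covers less than ``hr_wear_fraction``
    of its minutes, or when the observed day-window step total is at or below
    ``min_daily_steps`` (pro-rated on partial days). The step criterion is
    only assessed when at least half of the day-window step minutes are
    observed — all-missing step days carry no wear information of their own
    and are adjudicated by the HR criterion.

    Removal excises the day's samples from both recordings; it never flips
    the missing/observed status of any retained sample.
    """
    cfg = cfg or AnalysisConfig()
    log = ExclusionLog()
    hr_days = day_index(hr_rec.times)
    st_days = day_index(steps_rec.times)
    all_days = np.unique(np.concatenate([hr_days, st_days]))
    window_minutes = (cfg.day_window[1] - cfg.day_window[0]) * 60.0

    st_hours = hour_of_day(steps_rec.times)
    st_in_window = (st_hours >= cfg.day_window[0]) & (st_hours < cfg.day_window[1])

    bad_days = []
    for d in all_days:
        hsel = hr_days == d
        covered = int(hsel.sum())
        if covered:
            observed = int((~hr_rec.missing[hsel]).sum())
            if observed < cfg.hr_wear_fraction * covered:
                bad_days.append((d, "hr_wear", 100.0 * observed / covered))
                continue
        ssel = (st_days == d) & st_in_window
        w_covered = int(ssel.sum())
        if w_covered:
            obs_min = ssel & ~steps_rec.missing
            n_obs = int(obs_min.sum())
            if n_obs >= 0.5 * w_covered:
                total = float(steps_rec.values[obs_min].sum())
                threshold = cfg.min_daily_steps * (w_covered / window_minutes)
                if total <= threshold:
                    bad_days.append((d, "min_steps", total))

    bad_set = {d for d, _, _ in bad_days}
    for d, rule, value in bad_days:
        log.add(hr_rec.subject_id, "hr+steps", "day", rule, value,
                detail=str(np.datetime64(int(d), "D")))

    def _excise(rec: Recording, days: np.ndarray) -> Recording:
        keep = ~np.isin(days, list(bad_set)) if bad_set else np.ones(days.size, bool)
        retained = np.unique(days[keep])
        return Recording(
            rec.subject_id,
            rec.modality,
            rec.times[keep],
            rec.values[keep],
            rec.missing[keep],
            rec.grid_step,
            grid_start=rec.grid_start,
            retained_days=retained.astype("datetime64[D]"),
        )

    return _excise(hr_rec, hr_days), _excise(steps_rec, st_days), log


def exclude_recordings(
    recordings, cfg: AnalysisConfig | None = None
) -> tuple[list, ExclusionLog]:
    """Drop recordings whose missing fraction strictly exceeds the cap."""
    cfg = cfg or AnalysisConfig()
    log = ExclusionLog()
    kept = []
    for rec in recordings:
        frac = rec.missing_fraction
        if rec.n == 0 or frac > cfg.max_recording_loss_fraction:
            log.add(rec.subject_id, rec.modality, "recording", "max_loss",
                    100.0 * frac if rec.n else float("nan"))
        else:
            kept.append(rec)
    return kept, log


# ---------------------------------------------------------------------------
# cohort convenience wrapper
# ---------------------------------------------------------------------------


def preprocess_cohort(
    raw_series, cfg: AnalysisConfig | None = None
) -> tuple[dict, ExclusionLog]:
    """Run the full preprocessing chain over a collection of raw streams.

    Returns ``(recordings, log)`` where ``recordings`` maps modality to a list
    of retained :class:`Recording` objects.
    """
    cfg = cfg or AnalysisConfig()
    log = ExclusionLog()
    by_subject: dict[str, dict[str, RawSeries]] = {}
    for rs in raw_series:
        by_subject.setdefault(rs.subject_id, {})[rs.modality] = rs

    out: dict[str, list[Recording]] = {"glucose": [], "hr": [], "steps": []}
    for sid in sorted(by_subject):
        streams = by_subject[sid]
        if "glucose" in streams:
            try:
                out["glucose"].append(resample_glucose(streams["glucose"], cfg))
            except ValueError as err:
                log.add(sid, "glucose", "recording", "too_few_samples",
                        streams["glucose"].n, detail=str(err))
        hr_rec = None
        if "hr" in streams:
            hr_rec = define_hr_missing(streams["hr"])
        if "steps" in streams and hr_rec is not None:
            steps_rec = define_steps_missing(streams["steps"], hr_rec, cfg)
            hr_rec, steps_rec, day_log = filter_wear_days(hr_rec, steps_rec, cfg)
            log.extend(day_log)
            out["steps"].append(steps_rec)
        if hr_rec is not None:
            out["hr"].append(hr_rec)

    for modality in out:
        out[modality], excl = exclude_recordings(out[modality], cfg)
        log.extend(excl)
    return out, log
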