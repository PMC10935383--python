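"""Shared data containers for wearable-sensor missingness analysis.

All timestamps are timezone-naive wall-clock datetimes (``numpy.datetime64``):
the analysis groups samples by local clock hour and calendar day, so wall time
is the relevant axis and offsets are deliberately ignored.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("glucose", "hr", "steps")

#: native uniform-grid step per modality, in minutes
GRID_STEP_MINUTES = {"glucose": 15, "hr": 1, "steps": 1}

SECOND = np.timedelta64(1, "s")
MINUTE = np.timedelta64(60, "s")
HOUR = np.timedelta64(3600, "s")
DAY = np.timedelta64(86400, "s")


def as_datetime64(values) -> np.ndarray:
    """Coerce to a ``datetime64[s]`` array (second resolution)."""
    if isinstance(values, pd.DatetimeIndex):
        values = values.to_numpy()
    return np.asarray(values).astype("datetime64[s]")


def _epoch_seconds(times: np.ndarray) -> np.ndarray:
    return as_datetime64(times).astype(np.int64)


def hour_of_day(times: np.ndarray) -> np.ndarray:
    """Local clock hour (0-23) of each timestamp."""
    return (_epoch_seconds(times) // 3600) % 24


def day_index(times: np.ndarray) -> np.ndarray:
    """Calendar day as integer days since the epoch."""
    return _epoch_seconds(times) // 86400


def weekday(times: np.ndarray) -> np.ndarray:
    """Weekday with Monday = 0 ... Sunday = 6 (epoch day zero was a Thursday)."""
    return (day_index(times) + 3) % 7


@dataclass
class RawSeries:
    """One subject's raw stream for one modality, as delivered by the device.

    Timestamps must be strictly increasing; values are finite reals
    (glucose mmol/L, HR beats/min, steps counts/min).
    """

    subject_id: str
    modality: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.times = as_datetime64(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= np.timedelta64(0, "s")):
                raise ValueError(
                    f"timestamps must be strictly increasing for "
                    f"({self.subject_id}, {self.modality})"
                )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class Recording:
    """A uniform-grid recording with an explicit missing mask.

    ``times`` start on a regular grid of ``grid_step``; day-level exclusions may
    later excise whole calendar days, so after preprocessing the sample
    sequence can have day-sized holes while remaining grid-aligned.
    ``grid_start`` keeps the original anchor so measurement-day grouping is
    stable under excision.
    """

    subject_id: str
    modality: str
    times: np.ndarray
    values: np.ndarray
    missing: np.ndarray
    grid_step: np.timedelta64
    grid_start: np.datetime64 = None  # type: ignore[assignment]
    retained_days: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = as_datetime64(self.times)
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.times.shape == self.values.shape == self.missing.shape):
            raise ValueError("times, values and missing must have equal length")
        if self.grid_start is None:
            self.grid_start = self.times[0] if self.times.size else np.datetime64(0, "s")
        self.grid_start = np.datetime64(self.grid_start, "s")
        self.grid_step = np.timedelta64(self.grid_step).astype("timedelta64[s]")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean()) if self.n else float("nan")

    @property
    def percent_missing(self) -> float:
        return 100.0 * self.missing_fraction


@dataclass
class ExclusionEntry:
    subject_id: str
    modality: str
    scope: str  # "day" | "recording"
    rule: str
    value: float
    detail: str = ""


class ExclusionLog:
    """Chronological record of every excluded day or recording."""

    def __init__(self) -> None:
        self.entries: list[ExclusionEntry] = []

    def add(self, subject_id, modality, scope, rule, value, detail="") -> None:
        self.entries.append(
            ExclusionEntry(subject_id, modality, scope, rule, float(value), detail)
        )

    def extend(self, other: "ExclusionLog") -> None:
        self.entries.extend(other.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        cols = ["subject_id", "modality", "scope", "rule", "value", "detail"]
        return pd.DataFrame(
            [[getattr(e, c) for c in cols] for e in self.entries], columns=cols
        )


@dataclass
class GroundTruth:
    """Oracle mask of injected missingness for one simulated stream."""

    subject_id: str
    modality: str
    times: np.ndarray
    injected: np.ndarray
    mechanism: str

    def __post_init__(self) -> None:
        self.times = as_datetime64(self.times)
        self.injected = np.asarray(self.injected, dtype=bool)
        if self.times.shape != self.injected.shape:
            raise ValueError("mask length must equal grid length")
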