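"""Run configuration: every analysis threshold in one declarative object.

Defaults encode the published rule set for this kind of study: 15-min CGM grid
with the 18-min missingness rule, zero-coded activity-tracker streams, 70%
daily HR wear, >1000 steps per day-window, 50% recording-loss exclusion,
count-&le;5 gap-table truncation and a 0.01 significance level.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, field, fields

import yaml


@dataclass
class AnalysisConfig:
    # significance
    alpha: float = 0.01
    # CGM resampling
    grid_minutes: float = 15.0
    missing_threshold_minutes: float = 18.0
    cgm_missing_rule: str = "both_neighbors"  # or "long_interval"
    long_interval_minutes: float = 19.0
    # tracker wear rules
    hr_wear_fraction: float = 0.70
    min_daily_steps: float = 1000.0
    zero_step_run_minutes: int = 120
    day_window: tuple[int, int] = (8, 22)  # clock hours, [start, end)
    # recording-level exclusion
    max_recording_loss_fraction: float = 0.50
    # gap-table truncation
    frequency_cutoff_count: int = 5
    # goodness of fit
    reduce_dof_for_params: bool = False
    # dispersion
    measurement_day_mode: str = "rolling"  # or "calendar"
    bonferroni_across_groupings: bool = False
    # subgroups
    subgroup_loss_cuts: tuple[float, float] = (10.0, 20.0)
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for name in (
            "grid_minutes",
            "missing_threshold_minutes",
            "long_interval_minutes",
            "hr_wear_fraction",
            "min_daily_steps",
            "zero_step_run_minutes",
            "max_recording_loss_fraction",
            "frequency_cutoff_count",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cgm_missing_rule not in ("both_neighbors", "long_interval"):
            raise ValueError("cgm_missing_rule must be both_neighbors|long_interval")
        if self.measurement_day_mode not in ("rolling", "calendar"):
            raise ValueError("measurement_day_mode must be rolling|calendar")
        self.day_window = tuple(self.day_window)  # type: ignore[assignment]
        self.subgroup_loss_cuts = tuple(float(c) for c in self.subgroup_loss_cuts)  # type: ignore[assignment]
        if list(self.subgroup_loss_cuts) != sorted(self.subgroup_loss_cuts):
            raise ValueError("subgroup_loss_cuts must be ordered")
        if not (0 <= self.day_window[0] < self.day_window[1] <= 24):
            raise ValueError("day_window must be an ordered clock interval")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["day_window"] = list(self.day_window)
        d["subgroup_loss_cuts"] = list(self.subgroup_loss_cuts)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
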