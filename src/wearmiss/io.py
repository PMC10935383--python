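"""CSV / JSON readers and writers for the pipeline's interchange schemas.

Long-format raw CSV: ``subject_id, modality, timestamp, value`` (one row per
sample). Preprocessed recordings CSV adds a ``missing`` 0/1 column.
Reports are a JSON document (verdicts, fitted parameters, test p-values)
plus per-table CSVs; integers round-trip bit-exactly and reals to full
``repr`` precision.
"""
from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MODALITIES, GRID_STEP_MINUTES, MINUTE, RawSeries, Recording
from .cohort import CohortResult

__all__ = [
    "read_raw_series",
    "write_raw_series",
    "read_descriptives",
    "write_ground_truth",
    "read_recordings",
    "write_recordings",
    "write_report",
    "read_report",
]

RAW_COLUMNS = ("subject_id", "modality", "timestamp", "value")


def read_raw_series(path, schema: dict | None = None) -> list[RawSeries]:
    """Read a long-format raw CSV into one :class:`RawSeries` per
    (subject, modality); rows are sorted by time and duplicate timestamps are
    rejected."""
    schema = schema or {}
    colmap = {schema.get(c, c): c for c in RAW_COLUMNS}
    df = pd.read_csv(path)
    missing_cols = [c for c in colmap if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    df = df.rename(columns=colmap)[list(RAW_COLUMNS)]
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise ValueError(
            f"malformed timestamp at row {int(bad[0]) + 2}: "
            f"{df['timestamp'].iloc[bad[0]]!r}"
        )
    # local wall-clock time: drop any timezone offset
    try:
        ts = ts.dt.tz_localize(None)
    except TypeError:
        pass
    df["timestamp"] = ts
    dup = df.duplicated(subset=["subject_id", "modality", "timestamp"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate timestamp for ({row['subject_id']}, {row['modality']}) "
            f"at {row['timestamp']}"
        )
    df = df.sort_values(["subject_id", "modality", "timestamp"], kind="mergesort")
    out = []
    for (sid, modality), grp in df.groupby(["subject_id", "modality"], sort=True):
        out.append(
            RawSeries(str(sid), str(modality), grp["timestamp"].to_numpy(),
                      grp["value"].to_numpy())
        )
    return out


def write_raw_series(series, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": rs.subject_id,
                "modality": rs.modality,
                "timestamp": rs.times.astype("datetime64[s]").astype(str),
                "value": rs.values,
            }
        )
        for rs in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_descriptives(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truths, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": gt.subject_id,
                "modality": gt.modality,
                "timestamp": gt.times.astype("datetime64[s]").astype(str),
                "injected_missing": gt.injected.astype(int),
                "mechanism_label": gt.mechanism,
            }
        )
        for gt in truths
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_recordings(recordings_by_modality: dict, path) -> None:
    frames = []
    for recs in recordings_by_modality.values():
        for rec in recs:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "modality": rec.modality,
                        "timestamp": rec.times.astype("datetime64[s]").astype(str),
                        "value": rec.values,
                        "missing": rec.missing.astype(int),
                    }
                )
            )
    if not frames:
        raise ValueError("no recordings to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recordings(path) -> dict:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out: dict[str, list[Recording]] = {m: [] for m in MODALITIES}
    for (sid, modality), grp in df.groupby(["subject_id", "modality"], sort=True):
        grp = grp.sort_values("timestamp")
        step = np.timedelta64(GRID_STEP_MINUTES[str(modality)], "m").astype("timedelta64[s]")
        out[str(modality)].append(
            Recording(
                str(sid),
                str(modality),
                grp["timestamp"].to_numpy(),
                grp["value"].to_numpy(),
                grp["missing"].to_numpy().astype(bool),
                step,
            )
        )
    return out


# ---------------------------------------------------------------------------
# analysis report
# ---------------------------------------------------------------------------


def _fit_record(fit) -> dict:
    return {
        "family": fit.family,
        "params": [float(v) for v in fit.params],
        "loglik": fit.loglik,
        "chi2_stat": fit.chi2_stat,
        "chi2_p": fit.chi2_p,
        "dof": fit.dof,
        "sse": fit.sse,
        "converged": fit.converged,
        "degenerate": fit.degenerate,
    }


def write_report(result: CohortResult, outdir) -> Path:
    """Write the machine-readable report (JSON + CSVs) for a cohort analysis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not result.analyses:
        raise ValueError("empty cohort: nothing to report")

    doc: dict = {"config": result.config.to_dict(), "modalities": {}}
    for m, a in result.analyses.items():
        doc["modalities"][m] = {
            "n_recordings": a.n_recordings,
            "mechanism": a.verdict.final,
            "step1": a.step1,
            "step2": a.step2,
            "n_gaps": a.freq.total_gaps,
            "cutoff_size": a.freq.cutoff_size,
            "planck": _fit_record(a.planck_fit) if a.planck_fit else None,
            "family_ranking": [_fit_record(f) for f in a.family_fits],
            "kw": {g: {"H": r.kw_statistic, "p": r.kw_p}
                   for g, r in a.dispersion.items()},
            "significant_pairs": {
                g: [[pa, pb, p] for pa, pb, p in r.significant_pairs]
                for g, r in a.dispersion.items()
            },
        }
        pd.DataFrame(
            {
                "size": a.freq.sizes,
                "count": a.freq.counts,
                "retained": np.isin(a.freq.sizes, a.freq.retained_sizes).astype(int),
            }
        ).to_csv(outdir / f"gap_frequency_{m}.csv", index=False)
        for g, r in a.dispersion.items():
            pd.DataFrame(
                {
                    "group": r.groups,
                    "median_pct": r.medians,
                    "iqr_low": r.iqr_low,
                    "iqr_high": r.iqr_high,
                    "n_subjects": (~np.isnan(r.matrix)).sum(axis=0),
                }
            ).to_csv(outdir / f"dispersion_{m}_{g}.csv", index=False)
    doc["correlations"] = result.correlations.to_dict(orient="records")
    with open(outdir / "report.json", "w") as fh:
        json.dump(doc, fh, indent=1, allow_nan=True)
    return outdir / "report.json"


def read_report(outdir) -> dict:
    with open(Path(outdir) / "report.json") as fh:
        return json.load(fh)
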