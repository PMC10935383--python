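"""Missing-data dispersion over time groupings: the MAR screen.

Each recording's samples are sorted into time groups — hour of the day,
weekday, business days vs weekend, and measurement day — and the percentage
of missing samples per group is computed *per subject*. A Kruskal-Wallis
omnibus test asks whether median data loss differs across the groups, and
Dunn's rank-based post hoc test with Bonferroni correction (within each
grouping) identifies which pairs differ. Any surviving pair means missingness
depends on time: MAR. No surviving pair anywhere: MCAR.

Both tests are implemented here from the rank formulas (with tie correction)
rather than delegated, so that library implementations can serve as
independent cross-checks in the test-suite.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .config import AnalysisConfig
from .core import DAY, Recording, day_index, hour_of_day, weekday

__all__ = [
    "GROUPINGS",
    "assign_groups",
    "percent_missing_by_group",
    "dispersion_matrix",
    "kruskal_wallis",
    "dunn_posthoc",
    "analyze_dispersion",
    "classify_step2",
    "DispersionResult",
]

GROUPINGS = ("hour_of_day", "weekday", "business_weekend", "measurement_day")

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def assign_groups(rec: Recording, grouping: str) -> np.ndarray:
    """Integer group label for every sample of the recording.

    ``measurement_day`` counts rolling 24-h windows from the recording's
    original grid anchor by default (``cfg.measurement_day_mode='calendar'``
    switches to local calendar days elsewhere); labels are 1-based.
    """
    t = rec.times
    if grouping == "hour_of_day":
        return hour_of_day(t)
    if grouping == "weekday":
        return weekday(t)
    if grouping == "business_weekend":
        return (weekday(t) >= 5).astype(np.int64)  # 0 = business, 1 = weekend
    if grouping == "measurement_day":
        elapsed = (t - rec.grid_start).astype("timedelta64[s]").astype(np.int64)
        return 1 + elapsed // 86400
    raise ValueError(f"unknown grouping {grouping!r}")


def group_names(grouping: str, n_groups: int) -> list[str]:
    if grouping == "hour_of_day":
        return [f"{h:02d}:00" for h in range(24)]
    if grouping == "weekday":
        return list(WEEKDAY_NAMES)
    if grouping == "business_weekend":
        return ["business", "weekend"]
    return [f"day {d}" for d in range(1, n_groups + 1)]


def percent_missing_by_group(
    missing: np.ndarray, labels: np.ndarray, n_groups: int, offset: int = 0
) -> np.ndarray:
    """Per-group percentage of missing samples for one subject; NaN where the
    subject has no samples in a group."""
    labels = np.asarray(labels, dtype=np.int64) - offset
    totals = np.bincount(labels, minlength=n_groups).astype(float)
    miss = np.bincount(labels, weights=np.asarray(missing, dtype=float),
                       minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, 100.0 * miss / totals, np.nan)


def dispersion_matrix(
    recordings, grouping: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """(subjects x groups) percent-missing matrix for one grouping."""
    recs = list(recordings)
    if not recs:
        raise ValueError("no recordings")
    if grouping == "hour_of_day":
        n_groups, offset = 24, 0
    elif grouping == "weekday":
        n_groups, offset = 7, 0
    elif grouping == "business_weekend":
        n_groups, offset = 2, 0
    elif grouping == "measurement_day":
        n_groups = max(int(assign_groups(r, grouping).max()) for r in recs)
        offset = 1
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    mat = np.full((len(recs), n_groups), np.nan)
    for i, rec in enumerate(recs):
        labels = assign_groups(rec, grouping)
        mat[i] = percent_missing_by_group(rec.missing, labels, n_groups, offset)
    names = group_names(grouping, n_groups)
    subjects = [r.subject_id for r in recs]
    return mat, names, subjects


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _tie_term(pooled: np.ndarray) -> float:
    _, t = np.unique(pooled, return_counts=True)
    return float((t**3 - t).sum())


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square
    approximation with (groups - 1) degrees of freedom.

    ``groups`` is a sequence of 1-d arrays. All-identical data give
    ``H = 0, p = 1`` by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    k = len(groups)
    if k < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = scipy.stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    h /= correction
    return float(h), float(scipy.stats.chi2.sf(h, k - 1))


def dunn_posthoc(groups, correction: str = "bonferroni") -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Dunn z statistics on pooled ranks with tie correction.

    Returns ``(z, p_adj)`` as symmetric (k x k) matrices; ``p_adj`` is the
    two-sided normal p multiplied by the number of pairs (clipped at 1), with
    unit diagonal. Pairs involving a group with < 2 defined entries are NaN.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    k = len(groups)
    pooled = np.concatenate([g for g in groups]) if groups else np.empty(0)
    n = pooled.size
    z = np.zeros((k, k))
    p = np.full((k, k), np.nan)
    np.fill_diagonal(p, 1.0)
    if n == 0:
        return z, p
    ranks = scipy.stats.rankdata(pooled)
    mean_rank = np.full(k, np.nan)
    sizes = np.zeros(k, dtype=np.int64)
    start = 0
    for i, g in enumerate(groups):
        sizes[i] = g.size
        if g.size:
            mean_rank[i] = ranks[start : start + g.size].mean()
        start += g.size
    var_factor = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1)) if n > 1 else 0.0
    pairs = [(i, j) for i, j in itertools.combinations(range(k), 2)
             if sizes[i] >= 2 and sizes[j] >= 2]
    m = len(pairs)
    for i, j in pairs:
        denom = var_factor * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom <= 0:
            zij, pij = 0.0, 1.0
        else:
            zij = (mean_rank[i] - mean_rank[j]) / np.sqrt(denom)
            pij = min(1.0, 2.0 * scipy.stats.norm.sf(abs(zij)) * m)
        z[i, j] = z[j, i] = zij
        p[i, j] = p[j, i] = pij
    return z, p


@dataclass
class DispersionResult:
    """Per-grouping dispersion table and its omnibus / post hoc tests."""

    grouping: str
    matrix: np.ndarray  # subjects x groups, percent missing, NaN = no samples
    groups: list
    subjects: list
    medians: np.ndarray
    iqr_low: np.ndarray
    iqr_high: np.ndarray
    kw_statistic: float
    kw_p: float
    dunn_z: np.ndarray
    dunn_p: np.ndarray
    tested_groups: list
    significant_pairs: list  # (group_a, group_b, p_adj)

    @property
    def any_significant(self) -> bool:
        return len(self.significant_pairs) > 0


def analyze_dispersion(
    recordings, grouping: str, cfg: AnalysisConfig | None = None
) -> DispersionResult:
    """Build the dispersion table for one grouping and run KW + Dunn.

    Groups in which fewer than two subjects have samples are excluded from the
    tests (their entries are undefined, not zero)."""
    cfg = cfg or AnalysisConfig()
    mat, names, subjects = dispersion_matrix(recordings, grouping)
    with np.errstate(invalid="ignore"):
        medians = np.nanmedian(mat, axis=0)
        iqr_low = np.nanpercentile(mat, 25, axis=0)
        iqr_high = np.nanpercentile(mat, 75, axis=0)
    defined = (~np.isnan(mat)).sum(axis=0)
    tested = np.flatnonzero(defined >= 2)
    cols = [mat[:, j][~np.isnan(mat[:, j])] for j in tested]
    if tested.size >= 2:
        kw_h, kw_p = kruskal_wallis(cols)
        z_small, p_small = dunn_posthoc(cols)
    else:
        kw_h, kw_p = float("nan"), float("nan")
        z_small = np.zeros((tested.size, tested.size))
        p_small = np.full((tested.size, tested.size), np.nan)
    G = mat.shape[1]
    z = np.zeros((G, G))
    p = np.full((G, G), np.nan)
    np.fill_diagonal(p, 1.0)
    for a, ja in enumerate(tested):
        for b, jb in enumerate(tested):
            z[ja, jb] = z_small[a, b]
            p[ja, jb] = p_small[a, b]
    sig = [
        (names[ja], names[jb], float(p[ja, jb]))
        for ja, jb in itertools.combinations(tested, 2)
        if np.isfinite(p[ja, jb]) and p[ja, jb] < cfg.alpha
    ]
    return DispersionResult(
        grouping, mat, names, subjects, medians, iqr_low, iqr_high,
        float(kw_h), float(kw_p), z, p, [names[j] for j in tested], sig,
    )


def classify_step2(results, cfg: AnalysisConfig | None = None) -> str:
    """MAR iff any grouping has at least one Bonferroni-significant Dunn pair
    (the post hoc, not the omnibus, governs); else MCAR."""
    cfg = cfg or AnalysisConfig()
    results = list(results)
    if not results:
        raise ValueError("at least one grouping must be tested")
    if cfg.bonferroni_across_groupings:
        n_groupings = len(results)
        for r in results:
            if any(min(1.0, p * n_groupings) < cfg.alpha for _, _, p in r.significant_pairs):
                return "MAR"
        return "MCAR"
    return "MAR" if any(r.any_significant for r in results) else "MCAR"
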