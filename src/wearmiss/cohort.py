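"""Cohort-level synthesis: the two-step mechanism verdict, cross-modality
correlation of data loss, and subgroup analyses.

The decision tree: Step 1 (gap-size distribution vs Planck) screens for MNAR;
Step 2 (dispersion over time groupings) separates MAR from MCAR. MNAR
dominates the final verdict; otherwise Step 2 decides. Step 2 is always run —
the time structure of device-driven loss is informative even when the gap
distribution already gave MNAR.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .config import AnalysisConfig
from .core import Recording
from .dispersion import (
    GROUPINGS,
    DispersionResult,
    analyze_dispersion,
    classify_step2,
    dunn_posthoc,
    kruskal_wallis,
)
from .gaps import (
    DEFAULT_FAMILIES,
    GapFrequency,
    PmfFit,
    classify_step1,
    extract_gaps,
    fit_planck,
    pool_gap_frequency,
    rank_families,
)

__all__ = [
    "MechanismVerdict",
    "ModalityAnalysis",
    "CohortResult",
    "classify_mechanism",
    "analyze_modality",
    "analyze_cohort",
    "correlate_modal_loss",
    "split_subgroups",
    "compare_subgroups",
    "rmse_dispersion",
    "subgroup_gap_chisquare",
    "SUBGROUP_AXES",
]


# ---------------------------------------------------------------------------
# verdict
# ---------------------------------------------------------------------------


@dataclass
class MechanismVerdict:
    modality: str
    step1: str  # MNAR | M(C)AR | insufficient
    step2: str  # MAR | MCAR
    final: str  # MCAR | MAR | MNAR | indeterminate
    planck_p: float = float("nan")
    best_family: str | None = None
    n_gaps: int = 0
    significant_pairs: list = field(default_factory=list)


def classify_mechanism(step1: str, step2: str) -> str:
    """Combine the two screening steps; MNAR dominates."""
    if step1 == "insufficient":
        return "indeterminate"
    if step1 == "MNAR":
        return "MNAR"
    if step1 != "M(C)AR":
        raise ValueError(f"unknown step1 verdict {step1!r}")
    if step2 not in ("MAR", "MCAR"):
        raise ValueError(f"unknown step2 verdict {step2!r}")
    return step2


@dataclass
class ModalityAnalysis:
    """Everything computed for one modality."""

    modality: str
    n_recordings: int
    freq: GapFrequency
    planck_fit: PmfFit | None
    family_fits: list
    step1: str
    dispersion: dict  # grouping -> DispersionResult
    step2: str
    verdict: MechanismVerdict


def analyze_modality(
    recordings,
    cfg: AnalysisConfig | None = None,
    groupings=GROUPINGS,
    families=DEFAULT_FAMILIES,
) -> ModalityAnalysis:
    """Run both screening steps for one modality's preprocessed recordings."""
    cfg = cfg or AnalysisConfig()
    recs = list(recordings)
    if not recs:
        raise ValueError("no recordings to analyze")
    modality = recs[0].modality
    freq = pool_gap_frequency([extract_gaps(r.missing) for r in recs], cfg)

    planck = None
    fits: list[PmfFit] = []
    if not freq.insufficient:
        planck = fit_planck(freq, cfg)
        fits = rank_families(freq, families, cfg)
        step1 = classify_step1(freq, planck, cfg)
    else:
        step1 = "insufficient"

    disp = {g: analyze_dispersion(recs, g, cfg) for g in groupings}
    step2 = classify_step2(disp.values(), cfg)
    final = classify_mechanism(step1, step2)
    sig = [p for r in disp.values() for p in r.significant_pairs]
    verdict = MechanismVerdict(
        modality=modality,
        step1=step1,
        step2=step2,
        final=final,
        planck_p=planck.chi2_p if planck is not None else float("nan"),
        best_family=fits[0].family if fits else None,
        n_gaps=freq.total_gaps,
        significant_pairs=sig,
    )
    return ModalityAnalysis(
        modality, len(recs), freq, planck, fits, step1, disp, step2, verdict
    )


# ---------------------------------------------------------------------------
# cross-modality correlation
# ---------------------------------------------------------------------------


def correlate_modal_loss(loss_by_modality: dict) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of per-subject percent data loss.

    ``loss_by_modality`` maps modality -> {subject_id: percent_missing}.
    Pairs with fewer than 3 common subjects are flagged undefined.
    """
    rows = []
    for a, b in itertools.combinations(sorted(loss_by_modality), 2):
        common = sorted(set(loss_by_modality[a]) & set(loss_by_modality[b]))
        if len(common) < 3:
            rows.append((a, b, len(common), float("nan"), float("nan")))
            continue
        xa = np.asarray([loss_by_modality[a][s] for s in common], dtype=float)
        xb = np.asarray([loss_by_modality[b][s] for s in common], dtype=float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:  # constant ranks: undefined
            rows.append((a, b, len(common), float("nan"), float("nan")))
            continue
        rho, p = scipy.stats.spearmanr(xa, xb)
        rows.append((a, b, len(common), float(rho), float(p)))
    return pd.DataFrame(rows, columns=["modality_a", "modality_b", "n", "rho", "p"])


def loss_table(recordings_by_modality: dict) -> dict:
    """Per-subject percent missing for each modality."""
    return {
        m: {r.subject_id: r.percent_missing for r in recs}
        for m, recs in recordings_by_modality.items()
        if recs
    }


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

SUBGROUP_AXES = (
    "loss_amount", "gender", "age", "bmi", "hba1c", "years_diagnosis",
    "med_oral", "med_insulin", "med_other",
)


def _bin_label_loss(x: float, cuts) -> str:
    lo, hi = cuts
    if x < lo:
        return f"0-{lo:g}%"
    if x < hi:
        return f"{lo:g}-{hi:g}%"
    return f">{hi:g}%"


def split_subgroups(
    descriptives: pd.DataFrame,
    axis: str,
    loss_pct: dict | None = None,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Deterministic binning of subjects along one axis.

    Loss bins are left-closed ([0,10), [10,20), >=20 by default); age bins are
    <50, [50,60), [60,70] and >70 (the shared upper edge is right-closed, so
    age 70 falls in 60-70). Subjects with a missing covariate are excluded.
    Returns {bin label: list of subject ids}.
    """
    cfg = cfg or AnalysisConfig()
    bins: dict[str, list] = {}

    def put(label, sid):
        bins.setdefault(str(label), []).append(sid)

    for _, row in descriptives.iterrows():
        sid = row["subject_id"]
        if axis == "loss_amount":
            if loss_pct is None or sid not in loss_pct:
                continue
            put(_bin_label_loss(float(loss_pct[sid]), cfg.subgroup_loss_cuts), sid)
        elif axis == "gender":
            if pd.isna(row.get("gender")):
                continue
            put(row["gender"], sid)
        elif axis == "age":
            a = row.get("age_years")
            if pd.isna(a):
                continue
            if a < 50:
                put("<50", sid)
            elif a < 60:
                put("50-60", sid)
            elif a <= 70:
                put("60-70", sid)
            else:
                put(">70", sid)
        elif axis == "bmi":
            b = row.get("bmi")
            if pd.isna(b):
                continue
            put("<30" if b < 30 else ">=30", sid)
        elif axis == "hba1c":
            h = row.get("hba1c_mmol_mol")
            if pd.isna(h):
                continue
            put("<=53" if h <= 53 else ">53", sid)
        elif axis == "years_diagnosis":
            y = row.get("years_since_diagnosis")
            if pd.isna(y):
                continue
            if y < 10:
                put("0-10", sid)
            elif y < 20:
                put("10-20", sid)
            else:
                put(">20", sid)
        elif axis in ("med_oral", "med_insulin", "med_other"):
            v = row.get(axis)
            if pd.isna(v):
                continue
            put("yes" if int(v) else "no", sid)
        else:
            raise ValueError(f"unknown subgroup axis {axis!r}")
    return bins


@dataclass
class SubgroupTest:
    axis: str
    kind: str  # continuous | dichotomous
    statistic: float
    p: float
    p_adjusted: float
    posthoc_p: np.ndarray | None = None
    bin_labels: list = field(default_factory=list)
    unreliable: bool = False


def compare_subgroups(
    bins: dict,
    values: dict,
    kind: str,
    cfg: AnalysisConfig | None = None,
    n_tests_family: int = 1,
    axis: str = "",
) -> SubgroupTest:
    """Test whether a covariate (or loss) differs between subject bins.

    Continuous: Kruskal-Wallis omnibus + Dunn post hoc (Bonferroni within the
    axis). Dichotomous: contingency chi-square without continuity correction,
    flagged unreliable when any expected cell count is below 1. The omnibus p
    is additionally Bonferroni-multiplied by ``n_tests_family`` (the number of
    covariates screened together).
    """
    cfg = cfg or AnalysisConfig()
    labels = sorted(bins)
    groups = [
        np.asarray([values[s] for s in bins[lab] if s in values and not pd.isna(values[s])],
                   dtype=float)
        for lab in labels
    ]
    labels = [lab for lab, g in zip(labels, groups) if g.size > 0]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty bins")
    if kind == "continuous":
        h, p = kruskal_wallis(groups)
        _, padj_pairs = dunn_posthoc(groups)
        stat = h
        posthoc = padj_pairs
        unreliable = False
    elif kind == "dichotomous":
        cats = sorted({float(v) for g in groups for v in g})
        table = np.array([[int((g == c).sum()) for c in cats] for g in groups])
        stat, p, _, expected = scipy.stats.chi2_contingency(table, correction=False)
        posthoc = None
        unreliable = bool((expected < 1).any())
    else:
        raise ValueError("kind must be continuous|dichotomous")
    return SubgroupTest(
        axis=axis,
        kind=kind,
        statistic=float(stat),
        p=float(p),
        p_adjusted=float(min(1.0, p * n_tests_family)),
        posthoc_p=posthoc,
        bin_labels=labels,
        unreliable=unreliable,
    )


def rmse_dispersion(medians_a, medians_b) -> float:
    """RMSE between two dispersion-median vectors, each normalised to unit
    sum; a metric on the normalised vectors (symmetric, zero iff equal)."""
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("median vectors must have the same length")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a median vector sums to zero; RMSE undefined")
    a = a / a.sum()
    b = b / b.sum()
    return float(np.sqrt(np.mean((a - b) ** 2)))


def subgroup_gap_chisquare(
    sub_freq: GapFrequency, pooled_fit: PmfFit, cfg: AnalysisConfig | None = None
) -> tuple[float, float]:
    """One-way chi-square of a subgroup's retained gap counts against the
    pooled-cohort fitted pmf (renormalised over the subgroup's retained
    sizes): does the subgroup share the cohort's gap-size law?"""
    cfg = cfg or AnalysisConfig()
    if sub_freq.retained_sizes.size < 2:
        return float("nan"), float("nan")
    obs = sub_freq.retained_counts.astype(float)
    p = pooled_fit.pmf(sub_freq.retained_sizes)
    if p.sum() <= 0:
        return float("nan"), float("nan")
    p = p / p.sum()
    exp = obs.sum() * p
    stat = float(((obs - exp) ** 2 / exp).sum())
    dof = sub_freq.retained_sizes.size - 1
    return stat, float(scipy.stats.chi2.sf(stat, dof))


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    analyses: dict  # modality -> ModalityAnalysis
    correlations: pd.DataFrame
    config: AnalysisConfig

    @property
    def verdicts(self) -> dict:
        return {m: a.verdict for m, a in self.analyses.items()}


def analyze_cohort(
    recordings_by_modality: dict,
    cfg: AnalysisConfig | None = None,
    groupings=GROUPINGS,
    families=DEFAULT_FAMILIES,
) -> CohortResult:
    """Run the full two-step analysis for every modality present."""
    cfg = cfg or AnalysisConfig()
    present = {m: recs for m, recs in recordings_by_modality.items() if recs}
    if not present:
        raise ValueError("empty cohort: no recordings in any modality")
    analyses = {
        m: analyze_modality(recs, cfg, groupings=groupings, families=families)
        for m, recs in present.items()
    }
    correlations = correlate_modal_loss(loss_table(present))
    return CohortResult(analyses=analyses, correlations=correlations, config=cfg)
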