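"""Gap-size distribution statistics: the MNAR screen.

A *gap* is a maximal run of consecutive missing samples on a uniform grid.
Under a completely-random (Poisson-like) dropout process, gap sizes decline
exponentially; the reference model is therefore the Planck pmf — a normalised
discrete exponential

    P(k; lam) = (1 - e^{-lam}) e^{-lam (k - 1)},   k = 1, 2, ...

fitted by maximum likelihood to the cohort-pooled gap-size counts. A one-way
chi-square test of the observed counts against the fitted Planck pmf (after
truncating the table at the first size with a count <= 5, where expected
counts become unreliable) decides: a significant departure from exponential
decline implies the gaps are not produced by a random process, i.e. the
missingness is MNAR; otherwise it remains M(C)AR and the time-dispersion step
separates MAR from MCAR.

A registry of alternative discrete families (geometric, Zipf/zeta, Zipfian,
Yule-Simon, Boltzmann, ...) is fitted the same way and ranked by the sum of
squared errors between empirical and fitted probabilities; heavy-tailed
winners (e.g. Zipfian beating Planck) indicate an excess of extreme gap sizes
typical of device-driven loss.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .config import AnalysisConfig

__all__ = [
    "GapFrequency",
    "PmfFit",
    "extract_gaps",
    "pool_gap_frequency",
    "fit_planck",
    "fit_family",
    "rank_families",
    "chi_square_gof",
    "sse_of_fit",
    "classify_step1",
    "FAMILY_NAMES",
]


def extract_gaps(mask) -> np.ndarray:
    """Lengths of maximal missing runs, in grid samples (runs touching either
    end of the recording count)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty(0, dtype=np.int64)
    z = mask.astype(np.int8)
    d = np.diff(np.concatenate([[0], z, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return (ends - starts).astype(np.int64)


@dataclass
class GapFrequency:
    """Cohort-pooled gap-size counts with truncation metadata.

    ``sizes``/``counts`` is the full table; ``retained_*`` is the table after
    cutting at the first size whose count is <= the cutoff count (that size
    and everything larger are dropped; zero-count sizes below the cutoff stay,
    with count 0).
    """

    sizes: np.ndarray
    counts: np.ndarray
    total_gaps: int
    cutoff_size: int | None
    retained_sizes: np.ndarray
    retained_counts: np.ndarray

    @property
    def insufficient(self) -> bool:
        return self.retained_sizes.size == 0 or int(self.retained_counts.sum()) == 0

    @property
    def mean_size(self) -> float:
        if self.total_gaps == 0:
            return float("nan")
        return float((self.sizes * self.counts).sum() / self.total_gaps)


def pool_gap_frequency(gap_lists, cfg: AnalysisConfig | None = None) -> GapFrequency:
    """Sum gap counts over recordings and truncate the table.

    ``gap_lists`` is an iterable of per-recording gap-length arrays.
    """
    cfg = cfg or AnalysisConfig()
    arrays = [np.asarray(g, dtype=np.int64) for g in gap_lists]
    gaps = np.concatenate(arrays) if arrays else np.empty(0, dtype=np.int64)
    if gaps.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return GapFrequency(empty, empty, 0, None, empty, empty)
    max_size = int(gaps.max())
    counts_full = np.bincount(gaps, minlength=max_size + 1)[1:]  # index 0 -> size 1
    sizes_full = np.arange(1, max_size + 1, dtype=np.int64)
    observed = counts_full > 0

    cutoff: int | None = None
    for s in sizes_full[observed]:
        if counts_full[s - 1] <= cfg.frequency_cutoff_count:
            cutoff = int(s)
            break
    if cutoff is None:
        retained_sizes = sizes_full
    else:
        retained_sizes = sizes_full[: cutoff - 1]
    retained_counts = counts_full[: retained_sizes.size]
    return GapFrequency(
        sizes_full[observed],
        counts_full[observed],
        int(gaps.size),
        cutoff,
        retained_sizes,
        retained_counts.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# discrete-family registry
# ---------------------------------------------------------------------------
# Each family maps true gap sizes k >= 1 onto its natural support: families on
# {0, 1, ...} (or bounded {0..N}) are fitted on the shifted values k - 1;
# families whose support already starts at 1 (zipf, zipfian, logarithmic,
# yule_simon, uniform) use k directly. Bounded-support families take
# N = max retained size. "zeta" is the same infinite-support power law as
# "zipf" (kept as an alias because both names are in common use).


class _TruncatedDiscrete:
    """A discrete distribution renormalised onto the bounded support
    {0, ..., N}; used for families whose natural support is all integers
    (Skellam, discrete Laplace) so they remain valid ranking candidates."""

    def __init__(self, dist, N: int):
        self._dist = dist
        self._support = np.arange(0, N + 1)
        self._z = float(dist.pmf(self._support).sum())

    def pmf(self, x):
        x = np.asarray(x)
        inside = (x >= 0) & (x <= self._support[-1])
        with np.errstate(divide="ignore"):
            p = np.where(inside, self._dist.pmf(np.where(inside, x, 0)), 0.0)
        return p / self._z if self._z > 0 else p * 0.0

    def logpmf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.pmf(x))


def _loglik(dist, x: np.ndarray, c: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = dist.logpmf(x)
    lp = np.where(np.isfinite(lp), lp, -1e12)
    return float((c * lp).sum())


def _brent_fit(make_dist, bounds, x, c):
    res = scipy.optimize.minimize_scalar(
        lambda p: -_loglik(make_dist(p), x, c), bounds=bounds, method="bounded"
    )
    return (float(res.x),), bool(res.success)


def _nm_fit(make_dist, x0, x, c):
    res = scipy.optimize.minimize(
        lambda p: -_loglik(make_dist(p), x, c), x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    return tuple(float(v) for v in res.x), bool(res.success)


def _planck_mle(kbar: float) -> float:
    return float(np.log(kbar / (kbar - 1.0)))


def _fit_planck_family(x, c, N):
    # x holds the shifted sizes k - 1; the closed form uses the mean size kbar
    kbar = float((x * c).sum() / c.sum()) + 1.0
    if kbar <= 1.0:
        return (float("inf"),), True
    return (_planck_mle(kbar),), True


_EPS = 1e-9


def _registry():
    S = scipy.stats
    reg: dict[str, dict] = {}

    reg["planck"] = dict(
        shift=1, bounded=False,
        fit=_fit_planck_family,
        dist=lambda p, N: S.planck(p[0]),
        n_params=1,
    )
    reg["geometric"] = dict(
        shift=0, bounded=False,
        fit=lambda x, c, N: ((float(c.sum() / (x * c).sum()),), True),
        dist=lambda p, N: S.geom(p[0]),
        n_params=1,
    )
    reg["boltzmann"] = dict(
        shift=1, bounded=True,
        fit=lambda x, c, N: _brent_fit(lambda l: S.boltzmann(l, N), (1e-6, 20.0), x, c),
        dist=lambda p, N: S.boltzmann(p[0], N),
        n_params=1,
    )
    reg["poisson"] = dict(
        shift=1, bounded=False,
        fit=lambda x, c, N: ((float((x * c).sum() / c.sum()),), True),
        dist=lambda p, N: S.poisson(p[0]),
        n_params=1,
    )
    reg["logarithmic"] = dict(
        shift=0, bounded=False,
        fit=lambda x, c, N: _brent_fit(lambda p: S.logser(p), (_EPS, 1 - _EPS), x, c),
        dist=lambda p, N: S.logser(p[0]),
        n_params=1,
    )
    reg["zipf"] = dict(
        shift=0, bounded=False,
        fit=lambda x, c, N: _brent_fit(lambda a: S.zipf(a), (1.0 + 1e-6, 20.0), x, c),
        dist=lambda p, N: S.zipf(p[0]),
        n_params=1,
    )
    reg["zeta"] = dict(reg["zipf"])  # same law, common alternative name
    reg["zipfian"] = dict(
        shift=0, bounded=True,
        fit=lambda x, c, N: _brent_fit(lambda a: S.zipfian(a, N), (1e-6, 20.0), x, c),
        dist=lambda p, N: S.zipfian(p[0], N),
        n_params=1,
    )
    reg["yule_simon"] = dict(
        shift=0, bounded=False,
        fit=lambda x, c, N: _brent_fit(lambda a: S.yulesimon(a), (1e-3, 50.0), x, c),
        dist=lambda p, N: S.yulesimon(p[0]),
        n_params=1,
    )
    reg["uniform"] = dict(
        shift=0, bounded=True,
        fit=lambda x, c, N: ((), True),
        dist=lambda p, N: S.randint(1, N + 1),
        n_params=0,
    )
    reg["discrete_laplace"] = dict(
        shift=1, bounded=True,
        fit=lambda x, c, N: _brent_fit(
            lambda a: _TruncatedDiscrete(S.dlaplace(a), N), (1e-4, 20.0), x, c
        ),
        dist=lambda p, N: _TruncatedDiscrete(S.dlaplace(p[0]), N),
        n_params=1,
    )
    reg["negative_binomial"] = dict(
        shift=1, bounded=False,
        fit=lambda x, c, N: _nm_fit(
            lambda p: S.nbinom(np.exp(p[0]), 1.0 / (1.0 + np.exp(p[1]))),
            np.array([0.0, 0.0]), x, c,
        ),
        dist=lambda p, N: S.nbinom(np.exp(p[0]), 1.0 / (1.0 + np.exp(p[1]))),
        n_params=2,
    )
    reg["beta_binomial"] = dict(
        shift=1, bounded=True,
        fit=lambda x, c, N: _nm_fit(
            lambda p: S.betabinom(N, np.exp(p[0]), np.exp(p[1])),
            np.array([0.0, 0.5]), x, c,
        ),
        dist=lambda p, N: S.betabinom(N, np.exp(p[0]), np.exp(p[1])),
        n_params=2,
    )
    reg["skellam"] = dict(
        shift=1, bounded=True,
        fit=lambda x, c, N: _nm_fit(
            lambda p: _TruncatedDiscrete(S.skellam(np.exp(p[0]), np.exp(p[1])), N),
            np.array([0.5, -1.0]), x, c,
        ),
        dist=lambda p, N: _TruncatedDiscrete(S.skellam(np.exp(p[0]), np.exp(p[1])), N),
        n_params=2,
    )

    def _hyper_fit(x, c, N):
        # coarse integer grid over the population/success parameters
        best, best_ll = None, -np.inf
        for M in range(max(2 * N, 4), 4 * N + 5, max(N // 4, 1)):
            for n_good in range(N, M + 1, max(M // 12, 1)):
                ll = _loglik(scipy.stats.hypergeom(M, n_good, N), x, c)
                if ll > best_ll:
                    best, best_ll = (float(M), float(n_good)), ll
        return best or (float(2 * N), float(N)), best is not None

    reg["hypergeometric"] = dict(
        shift=1, bounded=True,
        fit=_hyper_fit,
        dist=lambda p, N: S.hypergeom(int(p[0]), int(p[1]), N),
        n_params=2,
    )
    return reg


_REGISTRY = _registry()
FAMILY_NAMES = tuple(_REGISTRY)

#: families fitted by default when ranking alternatives
DEFAULT_FAMILIES = (
    "planck", "geometric", "boltzmann", "poisson", "logarithmic", "zipf",
    "zipfian", "yule_simon", "uniform", "discrete_laplace",
    "negative_binomial", "beta_binomial",
)


@dataclass
class PmfFit:
    """A fitted discrete gap-size distribution with its goodness of fit."""

    family: str
    params: tuple
    loglik: float
    sse: float = float("nan")
    chi2_stat: float = float("nan")
    chi2_p: float = float("nan")
    dof: int = 0
    support_bound: int | None = None
    converged: bool = True
    degenerate: bool = False

    def pmf(self, sizes) -> np.ndarray:
        """Fitted probability of each (unshifted) gap size."""
        sizes = np.asarray(sizes, dtype=np.int64)
        spec = _REGISTRY[self.family]
        if self.degenerate:  # all mass on size 1
            return (sizes == 1).astype(float)
        dist = spec["dist"](self.params, self.support_bound)
        with np.errstate(divide="ignore"):
            return dist.pmf(sizes - spec["shift"])


def fit_family(
    family: str, freq: GapFrequency, cfg: AnalysisConfig | None = None
) -> PmfFit:
    """Numeric maximum-likelihood fit of one named family to pooled counts.

    Unbounded families are fitted on the full (pre-truncation) table; bounded
    families on the retained table (sizes beyond ``N`` are outside their
    support). Chi-square and SSE are filled in against the truncated table.
    """
    cfg = cfg or AnalysisConfig()
    if family not in _REGISTRY:
        raise ValueError(f"unknown family {family!r}")
    spec = _REGISTRY[family]
    if freq.insufficient:
        raise ValueError("no retained gap sizes to fit")
    N = int(freq.retained_sizes.max())
    if spec["bounded"]:
        sizes, counts = freq.retained_sizes, freq.retained_counts
        keep = counts > 0
        sizes, counts = sizes[keep], counts[keep]
    else:
        sizes, counts = freq.sizes, freq.counts
    x = sizes - spec["shift"]
    params, converged = spec["fit"](x, counts.astype(float), N)

    degenerate = bool(np.any(~np.isfinite(np.asarray(params, dtype=float)))) if params else False
    fit = PmfFit(
        family=family,
        params=params,
        loglik=float("nan"),
        support_bound=N,
        converged=converged,
        degenerate=degenerate,
    )
    if not degenerate:
        dist = spec["dist"](params, N)
        fit.loglik = _loglik(dist, x, counts.astype(float))
    fit.sse = sse_of_fit(freq, fit)
    fit.chi2_stat, fit.chi2_p, fit.dof = _chi_square(freq, fit, cfg, spec["n_params"])
    return fit


def fit_planck(freq: GapFrequency, cfg: AnalysisConfig | None = None) -> PmfFit:
    """Planck (normalised discrete exponential) MLE.

    The estimate has the closed form ``lam = ln(kbar / (kbar - 1))`` with
    ``kbar`` the count-weighted mean gap size; ``kbar == 1`` (all gaps of one
    sample) gives a degenerate fit, flagged as such.
    """
    return fit_family("planck", freq, cfg)


def rank_families(
    freq: GapFrequency, families=DEFAULT_FAMILIES, cfg: AnalysisConfig | None = None
) -> list[PmfFit]:
    """Fit several families and rank them by SSE (best first); fits that do
    not converge are excluded from the ranking."""
    fits = []
    for name in families:
        try:
            fit = fit_family(name, freq, cfg)
        except (ValueError, FloatingPointError):
            continue
        if fit.converged and np.isfinite(fit.sse):
            fits.append(fit)
    return sorted(fits, key=lambda f: f.sse)


def _renormalised_pmf(freq: GapFrequency, fit: PmfFit) -> np.ndarray:
    p = fit.pmf(freq.retained_sizes)
    total = p.sum()
    if total <= 0:
        raise ValueError("fitted pmf has no mass on the retained sizes")
    return p / total


def _chi_square(freq, fit, cfg, n_params):
    if freq.retained_sizes.size < 2:
        return float("nan"), float("nan"), 0
    obs = freq.retained_counts.astype(float)
    p = _renormalised_pmf(freq, fit)
    exp = np.maximum(obs.sum() * p, 1e-300)  # zero-mass bins -> huge statistic
    stat = float(((obs - exp) ** 2 / exp).sum())
    dof = int(freq.retained_sizes.size - 1)
    if cfg.reduce_dof_for_params:
        dof = max(dof - n_params, 1)
    return stat, float(scipy.stats.chi2.sf(stat, dof)), dof


def chi_square_gof(
    freq: GapFrequency, fit: PmfFit, cfg: AnalysisConfig | None = None
) -> tuple[float, float]:
    """One-way chi-square of the truncated table against the fitted pmf
    renormalised over the retained sizes (so observed and expected totals
    match). Undefined (NaN) with fewer than two retained sizes."""
    cfg = cfg or AnalysisConfig()
    spec = _REGISTRY[fit.family]
    stat, p, _ = _chi_square(freq, fit, cfg, spec["n_params"])
    return stat, p


def sse_of_fit(freq: GapFrequency, fit: PmfFit) -> float:
    """Sum of squared differences between the empirical probabilities of the
    retained sizes and the renormalised fitted pmf."""
    if freq.insufficient:
        return float("nan")
    obs = freq.retained_counts / freq.retained_counts.sum()
    p = _renormalised_pmf(freq, fit)
    return float(((obs - p) ** 2).sum())


def classify_step1(
    freq: GapFrequency, planck_fit: PmfFit, cfg: AnalysisConfig | None = None
) -> str:
    """MNAR iff the gap-size table departs significantly from the fitted
    Planck pmf (chi-square p < alpha); 'insufficient' when the test is
    undefined."""
    cfg = cfg or AnalysisConfig()
    if freq.insufficient or planck_fit.degenerate or not np.isfinite(planck_fit.chi2_p):
        return "insufficient"
    return "MNAR" if planck_fit.chi2_p < cfg.alpha else "M(C)AR"
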