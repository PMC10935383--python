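"""Bar / heatmap views of gap-size fits and dispersion tables."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dispersion import DispersionResult  # noqa: E402
from .gaps import GapFrequency  # noqa: E402


def plot_gap_fit(freq: GapFrequency, fits, path=None):
    """Empirical gap-size probabilities (bars) with fitted pmfs (lines)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    if freq.retained_sizes.size:
        emp = freq.retained_counts / max(int(freq.retained_counts.sum()), 1)
        ax.bar(freq.retained_sizes, emp, color="0.8", label="empirical")
        for fit in fits:
            p = fit.pmf(freq.retained_sizes)
            s = p.sum()
            if s > 0:
                ax.plot(freq.retained_sizes, p / s, marker="o", ms=3,
                        label=f"{fit.family} (SSE {fit.sse:.2g})")
    ax.set_xlabel("gap size (samples)")
    ax.set_ylabel("probability")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_dispersion(result: DispersionResult, path=None):
    """Median percent missing per time group with IQR bars, plus the Dunn
    adjusted-p matrix."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    x = np.arange(len(result.groups))
    err = np.vstack(
        [result.medians - result.iqr_low, result.iqr_high - result.medians]
    )
    ax1.bar(x, result.medians, yerr=np.nan_to_num(err), color="firebrick",
            error_kw={"lw": 0.8})
    ax1.set_xticks(x, result.groups, rotation=90, fontsize=7)
    ax1.set_ylabel("missing data (%)")
    ax1.set_title(f"{result.grouping} (KW p = {result.kw_p:.3g})")
    with np.errstate(divide="ignore"):
        logp = -np.log10(np.clip(result.dunn_p, 1e-12, 1.0))
    im = ax2.imshow(logp, cmap="viridis")
    ax2.set_xticks(x, result.groups, rotation=90, fontsize=6)
    ax2.set_yticks(x, result.groups, fontsize=6)
    fig.colorbar(im, ax=ax2, label="-log10 adjusted p")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
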