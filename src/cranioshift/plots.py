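"""Basic diagnostic figures: PC1-PC2 scatter and per-statistic histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import ComparisonResult
from .morphospace import Morphospace, ScoreTable

_COLORS = {"pre": "tab:red", "post": "tab:blue"}


def _hdr_mask(x: np.ndarray, y: np.ndarray, frac: float = 0.75) -> np.ndarray:
    """Empirical highest-density region: keep the ``frac`` of points with
    smallest Mahalanobis distance from the group mean."""
    pts = np.column_stack([x, y])
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    inv = np.linalg.pinv(cov)
    d = np.einsum("ij,jk,ik->i", pts - center, inv, pts - center)
    return d <= np.quantile(d, frac)


def plot_morphospace(scores: ScoreTable, space: Morphospace,
                     path: str | Path) -> None:
    """Scatter of the first two PCs with group means and an empirical 75%
    highest-density subset outlined per group."""
    fig, ax = plt.subplots(figsize=(6, 5))
    pct = space.percent_variance
    for period in ("pre", "post"):
        sub = scores.subset_period(period)
        if sub.scores.shape[0] == 0:
            continue
        x, y = sub.scores[:, 0], sub.scores[:, 1]
        c = _COLORS[period]
        ax.scatter(x, y, s=12, alpha=0.5, color=c, label=period)
        ax.scatter([x.mean()], [y.mean()], marker="+", s=160, color=c, zorder=3)
        if x.size >= 5:
            keep = _hdr_mask(x, y)
            ax.scatter(x[keep], y[keep], s=12, facecolors="none",
                       edgecolors=c, linewidths=0.8)
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_statistic_histograms(result: ComparisonResult, path: str | Path,
                              n_axes: int = 2) -> None:
    """Histograms of the subsampled post statistics with the pre-group
    value (arrow) and its estimation-error interval (horizontal line)."""
    if result.post_replicates is None:
        raise ValueError("comparison result carries no replicate data")
    n_axes = min(n_axes, len(result.axis_names))
    fig, axes = plt.subplots(n_axes, 3, figsize=(11, 3 * n_axes), squeeze=False)
    for k in range(n_axes):
        for s, stat in enumerate(result.stat_names):
            ax = axes[k][s]
            ax.hist(result.post_replicates[:, s, k], bins=40,
                    color="tab:blue", alpha=0.7)
            ymax = ax.get_ylim()[1]
            ax.annotate("", xy=(result.pre_value[s, k], 0),
                        xytext=(result.pre_value[s, k], 0.25 * ymax),
                        arrowprops=dict(color="tab:red", arrowstyle="-|>"))
            ax.plot([result.pre_lo[s, k], result.pre_hi[s, k]],
                    [0.02 * ymax] * 2, color="tab:red", lw=2)
            ax.set_title(f"{result.axis_names[k]} {stat}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
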