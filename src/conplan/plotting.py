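"""Optional matplotlib figures: performance-curve panels, rank maps and
range-size scatter.  Imported lazily so the core library has no hard
matplotlib dependency."""

from __future__ import annotations

import numpy as np

from .curves import PerformanceCurve
from .prioritize import RankMap


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_performance_curves(
    curve: PerformanceCurve,
    random_curve: tuple[np.ndarray, np.ndarray] | None = None,
    envelope: tuple[np.ndarray, np.ndarray] | None = None,
    title: str = "",
    path: str | None = None,
):
    """Mean curve per group (built-up dashed), optional random curve and
    its min/max envelope band."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    groups = sorted(set(curve.groups))
    for g in groups:
        members = [n for n, gg in zip(curve.names, curve.groups) if gg == g]
        style = {"linestyle": "--", "color": "0.4"} if g == "builtup" else {}
        ax.plot(curve.fractions_lost, curve.mean(members), label=g, **style)
    if random_curve is not None:
        ax.plot(random_curve[0], random_curve[1], ":", color="k", label="random")
        if envelope is not None:
            ax.fill_between(random_curve[0], envelope[0], envelope[1],
                            color="0.85", zorder=0)
    ax.set_xlabel("proportion of landscape lost")
    ax.set_ylabel("proportion of distributions remaining")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_rank_map(rank: RankMap, pa_mask: np.ndarray | None = None,
                  title: str = "", path: str | None = None):
    """Priority rank map (0 = lowest, 1 = highest importance); protected
    cells outlined in purple when a mask is given."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5.5, 5))
    shown = np.ma.masked_where(~rank.valid, rank.rank)
    im = ax.imshow(shown, cmap="viridis", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="priority rank")
    if pa_mask is not None:
        ax.contour(pa_mask.astype(float), levels=[0.5], colors="purple",
                   linewidths=0.8)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_range_vs_auc(table, title: str = "", path: str | None = None):
    """Feature AUC against range size (log x), one point per feature."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(table["range_size"], table["auc"], s=18)
    ax.set_xscale("log")
    ax.set_xlabel("range size")
    ax.set_ylabel("performance curve AUC")
    rho = table.attrs.get("spearman_rho")
    if rho is not None and np.isfinite(rho):
        ax.annotate(f"Spearman rho = {rho:.2f}", xy=(0.05, 0.05),
                    xycoords="axes fraction", fontsize=9)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
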