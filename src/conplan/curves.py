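"""Performance curves and their areas under the curve.

A performance curve tracks the proportion of a feature's original
distribution remaining in the landscape as the lowest-ranked fraction is
progressively lost: it starts at 1.0 with the full landscape, decreases
monotonically, and ends at 0.0 when everything is gone.  The AUC of a
feature's curve summarises how long it is retained by the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import FeatureStack
from .prioritize import RankMap


@dataclass
class PerformanceCurve:
    """Proportion remaining per feature at each fraction of landscape lost.

    ``fractions_lost`` has length n+1 (the exact removal staircase, 0 to
    1); ``proportion_remaining`` is (n+1, n_features).
    """

    fractions_lost: np.ndarray
    proportion_remaining: np.ndarray
    names: list[str]
    groups: list[str]

    def feature(self, name: str) -> np.ndarray:
        return self.proportion_remaining[:, self.names.index(name)]

    def mean(self, names: list[str] | None = None) -> np.ndarray:
        """Unweighted mean curve over a feature subset (default: all non-builtup)."""
        if names is None:
            idx = [i for i, g in enumerate(self.groups) if g != "builtup"]
        else:
            idx = [self.names.index(n) for n in names]
        if not idx:
            raise ValueError("empty feature subset")
        return self.proportion_remaining[:, idx].mean(axis=1)

    def on_grid(self, n_points: int = 1000) -> "PerformanceCurve":
        """Resample the staircase onto a uniform fraction grid (for plots/CSV)."""
        f = np.linspace(0.0, 1.0, n_points + 1)
        idx = np.searchsorted(self.fractions_lost, f, side="right") - 1
        return PerformanceCurve(f, self.proportion_remaining[idx],
                                list(self.names), list(self.groups))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportion_remaining, columns=self.names)
        df.insert(0, "fraction_lost", self.fractions_lost)
        return df


@dataclass
class CurveAUC:
    """Trapezoidal AUC per feature plus the mean over a named subset."""

    auc: dict[str, float]
    mean_auc: float
    subset: list[str]


def performance_curves(rank: RankMap, stack: FeatureStack) -> PerformanceCurve:
    """Exact staircase curves: remaining_j(k/n) after removing the k
    lowest-ranked cells.

    For a fraction f the proportion remaining of feature j is
    sum over cells with rank > f of q_ij / Q_j.
    """
    if rank.valid.shape != stack.shape or not np.array_equal(rank.valid, stack.valid):
        raise ValueError("rank map and stack are not co-registered")
    totals = stack.totals
    if (totals <= 0).any():
        bad = [stack.names[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"features with zero total distribution: {bad}")
    q = stack.feature_matrix()
    p = q / totals[None, :]
    order = np.argsort(rank.values_valid, kind="stable")  # removal order
    n = order.size
    removed = np.cumsum(p[order], axis=0)
    remaining = np.vstack([np.ones(p.shape[1]), 1.0 - removed])
    np.clip(remaining, 0.0, 1.0, out=remaining)
    remaining[-1] = 0.0  # everything gone at f = 1 by construction
    fractions = np.arange(n + 1) / n
    return PerformanceCurve(fractions, remaining, list(stack.names),
                            list(stack.groups))


def curve_auc(curve: PerformanceCurve, subset: list[str] | None = None) -> CurveAUC:
    """Trapezoidal area under each feature curve over fractions_lost in [0, 1]."""
    aucs = {
        name: float(np.trapezoid(curve.proportion_remaining[:, i],
                                 curve.fractions_lost))
        for i, name in enumerate(curve.names)
    }
    if subset is None:
        subset = [n for n, g in zip(curve.names, curve.groups) if g != "builtup"]
    if not subset:
        subset = list(curve.names)
    mean_auc = float(np.mean([aucs[n] for n in subset]))
    return CurveAUC(aucs, mean_auc, list(subset))


def auc_of_mean_curve(curve: PerformanceCurve,
                      names: list[str] | None = None) -> float:
    """AUC of the mean curve of a subset; equals the mean of member AUCs
    under the trapezoid rule."""
    return float(np.trapezoid(curve.mean(names), curve.fractions_lost))


def group_mean_curves(
    curve: PerformanceCurve, grouping: dict[str, str] | None = None
) -> PerformanceCurve:
    """Unweighted mean of member curves per group.

    ``grouping`` maps feature name to group label; by default the curve's
    own group labels are used.  An ``"__all__"`` column holds the overall
    mean over non-builtup features.
    """
    if grouping is None:
        grouping = dict(zip(curve.names, curve.groups))
    missing = [n for n in curve.names if n not in grouping]
    if missing:
        raise ValueError(f"features without a group: {missing}")
    group_order: list[str] = []
    for n in curve.names:
        g = grouping[n]
        if g not in group_order:
            group_order.append(g)
    cols = []
    for g in group_order:
        members = [n for n in curve.names if grouping[n] == g]
        cols.append(curve.mean(members))
    names = list(group_order)
    groups = list(group_order)
    non_builtup = [n for n, g in zip(curve.names, curve.groups) if g != "builtup"]
    if non_builtup:
        cols.append(curve.mean(non_builtup))
        names.append("__all__")
        groups.append("__all__")
    return PerformanceCurve(curve.fractions_lost.copy(), np.column_stack(cols),
                            names, groups)
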