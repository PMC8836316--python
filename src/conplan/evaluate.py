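"""Protected-area evaluation against a priority ranking.

Three diagnostics: (1) a chi-square goodness-of-fit test of the rank
values inside the protected areas against a uniform distribution — if
reserves had been placed indiscriminately, the rank histogram inside them
would match the (exactly uniform) landscape-wide histogram; (2) the
proportion of each feature's total distribution represented inside the
network, compared with the network's areal fraction (the random
expectation); (3) the relationship between each feature's range size and
its performance-curve AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curves import CurveAUC
from .grids import FeatureStack
from .prioritize import RankMap

#: smallest double distinguishable from 1 from below; the conventional
#: "p < 2.2e-16" reporting floor
P_FLOOR = 2.2e-16


@dataclass
class PAEvaluation:
    """Rank histogram inside the protected areas and its uniformity test."""

    bin_edges: np.ndarray
    observed_counts: np.ndarray
    expected_count: float
    chi2: float
    df: int
    p_value: float

    @property
    def p_text(self) -> str:
        return f"< {P_FLOOR:g}" if self.p_value < P_FLOOR else f"{self.p_value:.4g}"


def pa_rank_test(rank: RankMap, pa_mask: np.ndarray, n_bins: int = 10) -> PAEvaluation:
    """Chi-square test of in-PA rank frequencies against uniformity.

    Ranks in (0, 1] are binned into ``n_bins`` equal-width bins
    (half-open on the left, so rank 1.0 falls in the top bin); the
    expected count under uniformity is n_PA / n_bins and df = n_bins - 1.
    """
    pa_mask = np.asarray(pa_mask, dtype=bool)
    if pa_mask.shape != rank.valid.shape:
        raise ValueError("PA mask shape differs from the rank grid")
    vals = rank.rank[pa_mask & rank.valid]
    if vals.size == 0:
        raise ValueError("protected-area mask contains no valid cells")
    if vals.size < n_bins:
        raise ValueError("fewer in-PA cells than bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # bin k covers (k/n_bins, (k+1)/n_bins]
    idx = np.clip(np.ceil(vals * n_bins).astype(int) - 1, 0, n_bins - 1)
    observed = np.bincount(idx, minlength=n_bins).astype(float)
    chi2, p = stats.chisquare(observed)
    return PAEvaluation(
        bin_edges=edges,
        observed_counts=observed,
        expected_count=vals.size / n_bins,
        chi2=float(chi2),
        df=n_bins - 1,
        p_value=float(p),
    )


def representation_in_pa(stack: FeatureStack, pa_mask: np.ndarray) -> pd.DataFrame:
    """Per-feature proportion of the total distribution inside the network.

    Columns: feature, group, proportion_in_pa, random_expectation (the PA
    fraction of the valid area — the representation a feature spread
    uniformly over the landscape would attain).
    """
    pa_mask = np.asarray(pa_mask, dtype=bool)
    if pa_mask.shape != stack.shape:
        raise ValueError("PA mask shape differs from the stack grid")
    totals = stack.totals
    if (totals <= 0).any():
        bad = [stack.names[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"features with zero total: {bad}")
    inside = stack.data[:, pa_mask & stack.valid].sum(axis=1)
    pa_fraction = (pa_mask & stack.valid).sum() / stack.n_valid
    return pd.DataFrame({
        "feature": stack.names,
        "group": stack.groups,
        "proportion_in_pa": inside / totals,
        "random_expectation": pa_fraction,
    })


def representation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of in-PA representation per feature group."""
    return (
        table.groupby("group")["proportion_in_pa"]
        .agg(median="median",
             q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75),
             n="count")
        .reset_index()
    )


def range_sizes(stack: FeatureStack, mode: str = "species") -> np.ndarray:
    """Range size per feature.

    ``"species"``: the sum of suitability values over the landscape
    (continuous occurrence, no area factor).  ``"habitat"``: occupied
    area in km^2, i.e. the fractional cover summed and multiplied by the
    cell area.
    """
    totals = stack.totals
    if mode == "species":
        return totals
    if mode == "habitat":
        return totals * stack.cell_size**2
    raise ValueError(f"unknown range-size mode {mode!r}")


def range_vs_auc(
    stack: FeatureStack,
    auc: CurveAUC,
    mode: str = "species",
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Pair each feature's range size with its performance AUC.

    The returned frame carries a ``spearman_rho`` attribute (in
    ``DataFrame.attrs``) with the rank correlation over the listed
    features: the negative-trend diagnostic (small ranges retained
    longer => larger AUC).
    """
    names = features if features is not None else [
        n for n, g in zip(stack.names, stack.groups) if g != "builtup"
    ]
    sizes = range_sizes(stack.subset(names), mode)
    aucs = np.array([auc.auc[n] for n in names])
    df = pd.DataFrame({"feature": names, "range_size": sizes, "auc": aucs})
    if len(names) > 1 and np.ptp(sizes) > 0 and np.ptp(aucs) > 0:
        rho, p = stats.spearmanr(sizes, aucs)
        df.attrs["spearman_rho"] = float(rho)
        df.attrs["spearman_p"] = float(p)
    else:
        df.attrs["spearman_rho"] = float("nan")
        df.attrs["spearman_p"] = float("nan")
    return df
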