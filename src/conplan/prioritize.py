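"""Additive-benefit-function (ABF) greedy prioritization.

The landscape is ranked by iteratively discarding the cell whose removal
loses the least aggregate conservation value, retaining the most valuable
cells to the end.  With benefit function :math:`V(R) = R^z` applied to
each feature's remaining proportion :math:`R_j`, the marginal loss of
removing cell :math:`i` is

.. math::

    \\delta_i = \\sum_j w_j \\left[ R_j^z - (R_j - p_{ij})^z \\right],

where :math:`p_{ij} = q_{ij} / Q_j` is the cell's share of feature
:math:`j`'s total distribution and :math:`w_j` its weight.  Concave
:math:`V` (z < 1) emphasises feature-rich cells and retains range-
restricted features; negatively weighted layers (built-up classes) make
their cells cheapest to remove, excluding them from the priority areas.

The resulting rank map assigns each valid cell the normalized step at
which it would be retained: ranks are exactly :math:`\\{k/n\\}` for
:math:`k = 1..n`, with 1 the most important cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import FeatureStack, Grid

_CLAMP_TOL = 1e-12


@dataclass
class PrioritizerConfig:
    """Settings of the greedy removal.

    ``z`` is the benefit-function exponent (default 0.25, concave);
    ``batch_size`` the number of cells removed per re-evaluation of the
    marginal losses (1 = exact greedy); ``tie_rule`` breaks equal losses
    either by stable row-major index or by a seeded random permutation;
    ``mask`` (optional) marks cells forced to the top of the ranking —
    the protected-area expansion analysis.
    """

    z: float = 0.25
    batch_size: int = 1
    tie_rule: str = "stable_index"
    seed: int = 0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.tie_rule not in ("stable_index", "seeded_random"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass
class RankState:
    """Remaining proportion per feature and the removal order so far."""

    remaining: np.ndarray
    removed_order: list[int] = field(default_factory=list)


@dataclass
class RankMap:
    """Per-cell normalized removal rank in (0, 1] on valid cells.

    Higher rank = retained longer = higher conservation priority.  Ranks
    over the valid cells form the set {k/n : k = 1..n} (a normalized
    permutation) unless mask ranks were flattened to 1.
    """

    rank: np.ndarray
    valid: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    removal_order: np.ndarray | None = None  # flat valid-cell indices, removal order
    removal_delta: np.ndarray | None = None

    @property
    def values_valid(self) -> np.ndarray:
        """Rank values of valid cells in row-major cell order."""
        return self.rank[self.valid]

    def to_grid(self, name: str = "rank") -> Grid:
        return Grid(self.rank, self.valid, self.cell_size, self.origin, name)


def assign_aggregate_weights(
    stack: FeatureStack,
    group_weights: dict[str, float],
    builtup_total: float = -1.0,
) -> FeatureStack:
    """Spread group-level weights equally over each group's members.

    A group with aggregate weight ``W`` and ``k`` members gives each
    member ``W / k``, so differently sized feature groups contribute
    equally to the prioritization.  The ``"builtup"`` group receives the
    cumulative negative weight ``builtup_total`` split equally (and must
    not appear in ``group_weights``).
    """
    counts: dict[str, int] = {}
    for g in stack.groups:
        counts[g] = counts.get(g, 0) + 1
    for g, w in group_weights.items():
        if counts.get(g, 0) == 0 and w != 0:
            raise ValueError(f"group {g!r} has no members but nonzero weight")
    missing = [g for g in counts if g != "builtup" and g not in group_weights]
    if missing:
        raise ValueError(f"groups without an aggregate weight: {missing}")
    weights = np.empty(stack.n_features)
    for i, g in enumerate(stack.groups):
        if g == "builtup":
            weights[i] = builtup_total / counts[g]
        else:
            weights[i] = group_weights[g] / counts[g]
    return stack.with_weights(weights)


def _proportions(stack: FeatureStack) -> np.ndarray:
    """p_ij = q_ij / Q_j over valid cells; zero-total features contribute 0."""
    q = stack.feature_matrix()
    totals = stack.totals
    p = np.zeros_like(q)
    nz = totals > 0
    p[:, nz] = q[:, nz] / totals[nz]
    return p


def marginal_loss(
    cell: int, stack: FeatureStack, state: RankState, z: float
) -> float:
    """Marginal loss delta_i of removing one valid cell (flat valid-cell index)."""
    if cell in state.removed_order:
        raise ValueError(f"cell {cell} has already been removed")
    p = _proportions(stack)[cell]
    return float(_delta(p[None, :], state.remaining, stack.weights, z)[0])


def _delta(p: np.ndarray, remaining: np.ndarray, weights: np.ndarray,
           z: float) -> np.ndarray:
    """Vectorised delta_i for rows of p against the current remaining vector."""
    after = remaining[None, :] - p
    after = np.where(after > 0, after, np.where(after > -_CLAMP_TOL, 0.0, np.nan))
    if np.isnan(after).any():
        raise FloatingPointError("remaining proportion fell below a cell share")
    return (np.power(remaining, z)[None, :] - np.power(after, z)) @ weights


def _greedy_order(
    p: np.ndarray,
    weights: np.ndarray,
    cfg: PrioritizerConfig,
    candidates: np.ndarray,
    remaining: np.ndarray,
) -> list[int]:
    """Greedy removal order of `candidates`, mutating `remaining` in place.

    Re-evaluates the marginal losses of all still-present candidates every
    ``batch_size`` removals; within a batch, cells leave in ascending
    order of their (stale) losses.
    """
    alive = candidates.copy()
    if cfg.tie_rule == "seeded_random":
        perm = np.random.default_rng(cfg.seed).permutation(p.shape[0])
    order: list[int] = []
    while alive.size:
        d = _delta(p[alive], remaining, weights, cfg.z)
        if cfg.tie_rule == "seeded_random":
            take = np.lexsort((perm[alive], d))
        else:
            take = np.argsort(d, kind="stable")
        take = take[: cfg.batch_size]
        removed = alive[take]
        order.extend(int(i) for i in removed)
        remaining -= p[removed].sum(axis=0)
        np.clip(remaining, 0.0, None, out=remaining)
        keep = np.ones(alive.size, dtype=bool)
        keep[take] = False
        alive = alive[keep]
    return order


def rank_abf(stack: FeatureStack, cfg: PrioritizerConfig | None = None) -> RankMap:
    """Rank all valid cells by iterative ABF removal.

    When ``cfg.mask`` is set, every unmasked cell is removed before any
    masked cell, so the mask occupies the top ranks (protected-area
    expansion analysis); within each stratum the ordering is the ABF
    greedy order.
    """
    cfg = cfg or PrioritizerConfig()
    if not (stack.weights > 0).any():
        raise ValueError("stack needs at least one positively weighted feature")
    p = _proportions(stack)
    w = stack.weights
    if not (p[:, w > 0] > 0).any():
        raise ValueError("all positively weighted features are zero everywhere")
    n = p.shape[0]
    remaining = np.ones(stack.n_features)

    if cfg.mask is not None:
        mask = np.asarray(cfg.mask, dtype=bool)
        if mask.shape != stack.shape:
            raise ValueError("mask shape differs from the stack grid")
        mask_v = mask[stack.valid]
        if mask_v.all():
            raise ValueError("mask covers every valid cell; nothing to rank below it")
        strata = [np.flatnonzero(~mask_v), np.flatnonzero(mask_v)]
    else:
        strata = [np.arange(n)]

    order: list[int] = []
    for candidates in strata:
        order.extend(_greedy_order(p, w, cfg, candidates, remaining))

    order_arr = np.asarray(order)
    ranks_flat = np.empty(n)
    ranks_flat[order_arr] = np.arange(1, n + 1) / n
    rank = np.full(stack.shape, np.nan)
    rank[stack.valid] = ranks_flat
    return RankMap(rank, stack.valid.copy(), stack.cell_size, stack.origin,
                   removal_order=order_arr)


def rank_with_mask(
    stack: FeatureStack,
    mask: np.ndarray,
    cfg: PrioritizerConfig | None = None,
    flatten_mask_rank: bool = False,
) -> RankMap:
    """ABF ranking with protected cells forced to the top ranks.

    ``flatten_mask_rank=True`` additionally sets every masked cell's rank
    to exactly 1.0 (the ranking is then no longer a permutation; use it
    only for map output).
    """
    cfg = cfg or PrioritizerConfig()
    cfg = PrioritizerConfig(cfg.z, cfg.batch_size, cfg.tie_rule, cfg.seed, mask)
    result = rank_abf(stack, cfg)
    if flatten_mask_rank:
        result.rank[np.asarray(mask, bool) & stack.valid] = 1.0
    return result
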