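"""Synthetic landscapes, feature stacks and protected-area masks.

The generators emulate the statistical structure the prioritization and
surrogacy analyses assume, at desk scale:

* continuous 0-1 suitability surfaces (species distribution model output)
  with a wide spread of range sizes, where small-range features co-occur
  in shared richness hotspots;
* a categorical habitat mosaic at a finer resolution than the analysis
  grid, including a few clustered "built-up" classes;
* a protected-area mask whose placement can be biased toward
  high-priority cells.

Every generator is a pure function of its inputs and a seed: calling it
twice yields byte-identical output.  Random fields are built by Gaussian
smoothing of seeded white noise and rescaled to [0, 1].
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import FeatureStack, Grid, GridError


@dataclass
class StudyRegion:
    """The analysis grid: dimensions, cell area and the valid-cell mask."""

    n_rows: int
    n_cols: int
    cell_area: float = 1.0  # km^2
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("region dimensions must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("valid_mask shape inconsistent with dimensions")
        if not self.valid_mask.any():
            raise ValueError("region must contain at least one valid cell")

    @property
    def cell_size(self) -> float:
        return float(np.sqrt(self.cell_area))

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class SynthConfig:
    """Knobs of the synthetic feature generator.

    ``range_size_spread`` is the requested ratio between the largest and
    smallest feature total; ``smoothness`` the autocorrelation length in
    cells; ``hotspot_overlap`` the probability that a small-range feature
    is anchored on a shared hotspot rather than a random location;
    ``pa_value_bias`` controls how strongly protected-area placement
    favours high-rank cells (0 = uniformly random).
    """

    seed: int = 0
    n_species: int = 12
    n_habitat_classes: int = 8
    n_builtup_classes: int = 2
    range_size_spread: float = 10.0
    smoothness: float = 2.0
    hotspot_overlap: float = 0.7
    pa_coverage: float = 0.23
    pa_value_bias: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_habitat_classes) < 1 or self.n_builtup_classes < 0:
            raise ValueError("counts must be >= 1 (builtup >= 0)")
        if not (0.0 <= self.hotspot_overlap <= 1.0):
            raise ValueError("hotspot_overlap must lie in [0, 1]")
        if not (0.0 < self.pa_coverage < 1.0):
            raise ValueError("pa_coverage must lie in (0, 1)")
        if self.range_size_spread <= 0 or self.smoothness <= 0:
            raise ValueError("range_size_spread and smoothness must be positive")
        if self.pa_value_bias < 0:
            raise ValueError("pa_value_bias must be >= 0")


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded white noise smoothed to autocorrelation length sigma, rescaled to [0,1]."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi > lo:
        f = (f - lo) / (hi - lo)
    else:
        f = np.full(shape, 0.5)
    return f


def gen_region(
    n_rows: int, n_cols: int, seed: int, valid_fraction: float = 1.0,
    cell_area: float = 1.0,
) -> StudyRegion:
    """Generate a study region whose valid cells form one connected blob.

    The blob is grown greedily from the maximum of a smoothed random
    field, always absorbing the frontier cell with the highest field
    value, until it covers ``round(valid_fraction * n_cells)`` cells.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("region must be at least 2 x 2")
    if not (0.0 < valid_fraction <= 1.0):
        raise ValueError("valid_fraction must lie in (0, 1]")
    if valid_fraction == 1.0:
        return StudyRegion(n_rows, n_cols, cell_area)
    rng = np.random.default_rng(seed)
    f = _smooth_field((n_rows, n_cols), max(2.0, min(n_rows, n_cols) / 6), rng)
    target = max(1, round(valid_fraction * n_rows * n_cols))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    start = np.unravel_index(np.argmax(f), f.shape)
    # grow by priority (max field value on the frontier)
    heap = [(-f[start], start)]
    seen = {start}
    count = 0
    while heap and count < target:
        _, (r, c) = heapq.heappop(heap)
        mask[r, c] = True
        count += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and (nr, nc) not in seen:
                seen.add((nr, nc))
                heapq.heappush(heap, (-f[nr, nc], (nr, nc)))
    return StudyRegion(n_rows, n_cols, cell_area, mask)


def gen_habitat_mosaic(
    region: StudyRegion, n_classes: int, subgrid_factor: int, seed: int,
    smoothness: float | None = None,
    class_weights: np.ndarray | None = None,
) -> Grid:
    """Generate a categorical habitat mosaic at ``subgrid_factor`` x finer
    resolution than the analysis grid.

    Each class gets a smoothed random field on the fine grid; every fine
    cell takes the argmax class (a softened Voronoi mosaic with contiguous
    patches).  ``class_weights`` (default all 1) multiply each class's
    field before the argmax: weights below 1 shrink a class to small
    clustered patches — used for built-up classes.  Any class that loses
    everywhere is planted at its field's maximum so that all declared
    classes occur.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if subgrid_factor < 1:
        raise ValueError("subgrid_factor must be >= 1")
    fine_shape = (region.n_rows * subgrid_factor, region.n_cols * subgrid_factor)
    fine_valid = np.repeat(
        np.repeat(region.valid_mask, subgrid_factor, 0), subgrid_factor, 1
    )
    n_fine_valid = int(fine_valid.sum())
    if n_classes > n_fine_valid:
        raise ValueError(
            f"{n_classes} classes cannot fit in {n_fine_valid} fine cells"
        )
    rng = np.random.default_rng(seed)
    sigma = (smoothness if smoothness is not None else 1.5) * subgrid_factor
    fields = np.stack([_smooth_field(fine_shape, sigma, rng) for _ in range(n_classes)])
    if class_weights is not None:
        cw = np.asarray(class_weights, dtype=float)
        if cw.shape != (n_classes,):
            raise ValueError("class_weights must have one entry per class")
        fields = fields * cw[:, None, None]
    labels = np.argmax(fields, axis=0)
    counts = np.bincount(labels[fine_valid], minlength=n_classes)
    for c in range(n_classes):
        if counts[c] == 0:
            # plant at the class's best cell that is not another class's
            # last remaining occurrence
            flat = np.where(fine_valid.ravel(), fields[c].ravel(), -np.inf)
            for pos in np.argsort(flat)[::-1]:
                old = labels.ravel()[pos]
                if counts[old] >= 2:
                    labels.ravel()[pos] = c
                    counts[old] -= 1
                    counts[c] += 1
                    break
    fine_cell_size = region.cell_size / subgrid_factor
    return Grid(labels.astype(np.int64), fine_valid, fine_cell_size,
                (0.0, region.n_rows * region.cell_size), "habitat_mosaic")


def gen_species_stack(
    region: StudyRegion,
    cfg: SynthConfig,
    habitat_fracs: FeatureStack | None = None,
) -> FeatureStack:
    """Generate continuous suitability surfaces with a controlled spread of
    range sizes.

    Feature ``j`` is a Gaussian occupancy kernel around a centre, modulated
    by a smoothed noise texture and rescaled to peak 1.  Target totals are
    log-spaced so the largest/smallest ratio is ``range_size_spread``.
    With probability ``hotspot_overlap`` (scaled by how range-restricted
    the feature is) the centre is drawn from a small shared set of hotspot
    locations, so small-range features pile up in richness hotspots.  When
    fractional habitat layers are supplied, each species is tied to one
    habitat class and its suitability is boosted where that class covers
    more of the cell.
    """
    rng = np.random.default_rng(cfg.seed)
    nr, nc = region.n_rows, region.n_cols
    mask = region.valid_mask
    n_valid = region.n_valid
    m = cfg.n_species

    # log-spaced target totals (in cells); largest capped well below region size
    a_max = max(6.0, 0.35 * n_valid)
    a_min = max(3.0, a_max / cfg.range_size_spread)
    if m > 1:
        targets = a_min * (a_max / a_min) ** (np.arange(m) / (m - 1))
    else:
        targets = np.array([np.sqrt(a_min * a_max)])

    valid_rc = np.argwhere(mask)
    n_hot = max(1, min(3, n_valid))
    hot_idx = rng.choice(len(valid_rc), size=n_hot, replace=False)
    hotspots = valid_rc[hot_idx]

    rr, cc = np.mgrid[0:nr, 0:nc]
    layers = np.zeros((m, nr, nc))
    # most range-restricted feature -> highest chance of sitting on a hotspot
    restriction = 1.0 - (np.arange(m) / max(m - 1, 1))
    habitat_class = None
    if habitat_fracs is not None:
        # rarest habitat class to the most range-restricted species (the
        # wetland-bird pattern): class ranks follow the species' size rank,
        # with occasional random reassignment
        by_rarity = np.argsort(habitat_fracs.totals)
        n_cls = habitat_fracs.n_features
        habitat_class = np.array([
            by_rarity[rng.integers(n_cls)] if rng.random() < 0.3
            else by_rarity[min(int(j / m * n_cls), n_cls - 1)]
            for j in range(m)
        ])

    for j in range(m):
        # centre sampling weight over valid cells: the assigned habitat's
        # cover (species live in their habitat), sharpened toward a shared
        # hotspot kernel for range-restricted species
        w_centre = np.ones(len(valid_rc))
        if habitat_fracs is not None:
            frac_c = habitat_fracs.data[habitat_class[j]]
            w_centre = frac_c[mask] + 1e-9
        p_hot = cfg.hotspot_overlap * restriction[j]
        if rng.random() < p_hot:
            base = hotspots[rng.integers(n_hot)]
            d2h = ((valid_rc - base) ** 2).sum(axis=1)
            kern_sigma = max(cfg.smoothness, 1.0)
            w_centre = w_centre * np.exp(-d2h / (2 * (2 * kern_sigma) ** 2))
        w_centre = w_centre / w_centre.sum()
        centre = valid_rc[rng.choice(len(valid_rc), p=w_centre)].astype(float)
        sigma = np.sqrt(targets[j] / (2 * np.pi))
        d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
        bump = np.exp(-d2 / (2 * sigma**2))
        texture = _smooth_field((nr, nc), cfg.smoothness, rng)
        suit = bump * (0.5 + 0.5 * texture)
        if habitat_fracs is not None:
            # continuous model-like output: a low habitat-tracking floor
            # everywhere, high suitability in the core range
            frac = habitat_fracs.data[habitat_class[j]]
            suit = np.maximum(suit * (0.15 + 0.85 * frac),
                              0.15 * frac * texture)
        # normalise to the target total so the requested range-size spread
        # is realised; the [0,1] clip may shave a little off large peaks
        s = suit[mask].sum()
        if s > 0:
            suit = suit * (targets[j] / s)
        suit = np.where(mask, np.clip(suit, 0.0, 1.0), 0.0)
        layers[j] = suit

    names = [f"sp{j:03d}" for j in range(m)]
    groups = ["species"] * m
    return FeatureStack(layers, names, groups, np.ones(m), mask,
                        region.cell_size, (0.0, nr * region.cell_size))


def gen_pa_mask(
    region: StudyRegion,
    rank: np.ndarray | None,
    coverage: float,
    bias: float,
    seed: int,
) -> np.ndarray:
    """Generate a protected-area mask covering ``coverage`` of valid cells.

    With ``bias == 0`` cells are sampled uniformly; with ``bias > 0`` a
    cell's inclusion weight is ``exp(bias * rank)``, so the mask seeks
    high-priority cells (weighted sampling without replacement via the
    Gumbel top-k trick).
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    if bias < 0:
        raise ValueError("bias must be >= 0")
    if bias > 0 and rank is None:
        raise ValueError("a rank map is required when bias > 0")
    rng = np.random.default_rng(seed)
    mask = region.valid_mask
    n_valid = region.n_valid
    k = max(1, round(coverage * n_valid))
    if bias > 0:
        rank_vals = np.asarray(rank, dtype=float)[mask]
        logw = bias * rank_vals
    else:
        logw = np.zeros(n_valid)
    keys = logw + rng.gumbel(size=n_valid)
    chosen = np.argsort(keys)[::-1][:k]
    pa = np.zeros_like(mask)
    flat_idx = np.flatnonzero(mask.ravel())[chosen]
    pa.ravel()[flat_idx] = True
    return pa
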