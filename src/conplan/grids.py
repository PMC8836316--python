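"""Gridded layers and feature stacks.

All layers in an analysis are co-registered: same shape, same cell size,
same origin and same valid mask.  The convention is row-major with row 0
at the north edge, 0-based cell addressing, and half-open extents; the
``origin`` is the outer (north-west) corner of the top-left cell.

Two on-disk formats are supported: the ESRI ASCII grid (plain text,
lossless round trip) and GeoTIFF written through :mod:`tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

log = logging.getLogger(__name__)

#: nodata sentinel used by the ASCII dialect
NODATA = -9999.0

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridError(ValueError):
    """Malformed grid file or incompatible layers."""


@dataclass
class Grid:
    """A single co-registered raster layer.

    ``values`` may be continuous (float) or categorical (integer);
    ``valid`` marks analysable cells — everything else is nodata.
    """

    values: np.ndarray
    valid: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2:
            raise GridError("grid values must be a 2-D matrix")
        if self.values.shape != self.valid.shape:
            raise GridError(
                f"values shape {self.values.shape} != valid mask shape {self.valid.shape}"
            )
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_categorical(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    def total(self) -> float:
        """Sum of values over valid cells."""
        return float(self.values[self.valid].sum())

    def same_registration(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


def _check_coregistered(grids: list[Grid]) -> None:
    g0 = grids[0]
    for g in grids[1:]:
        if g.shape != g0.shape:
            raise GridError(f"layer shape mismatch: {g.shape} vs {g0.shape}")
        if not np.isclose(g.cell_size, g0.cell_size):
            raise GridError(
                f"cell size mismatch: {g.cell_size} vs {g0.cell_size}"
            )
        if not np.allclose(g.origin, g0.origin):
            raise GridError(f"origin mismatch: {g.origin} vs {g0.origin}")
        if not np.array_equal(g.valid, g0.valid):
            raise GridError("valid masks differ between layers")


@dataclass
class FeatureStack:
    """A set of co-registered feature layers with names, groups and weights.

    ``data`` has shape ``(n_features, n_rows, n_cols)``.  ``groups`` carries
    an arbitrary label per feature (e.g. a breeding-habitat group,
    ``"habitat"``, or ``"builtup"`` for negatively weighted exclusion
    layers).  ``totals`` (:math:`Q_j`) is each feature's sum over valid
    cells and is the normaliser of the per-cell proportions
    :math:`p_{ij} = q_{ij} / Q_j` used throughout the prioritization.
    """

    data: np.ndarray
    names: list[str]
    groups: list[str]
    weights: np.ndarray
    valid: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        m = self.data.shape[0]
        if not (len(self.names) == len(self.groups) == self.weights.size == m):
            raise GridError("names, groups, weights and data must have equal length")
        if self.data.shape[1:] != self.valid.shape:
            raise GridError("layer shape inconsistent with valid mask")
        if len(set(self.names)) != m:
            raise GridError("feature names must be unique")
        bad = (self.weights > 0) & (self.totals <= 0)
        if bad.any():
            which = [self.names[i] for i in np.flatnonzero(bad)]
            raise GridError(f"positively weighted features with zero total: {which}")

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def totals(self) -> np.ndarray:
        """Per-feature totals Q_j over valid cells."""
        return self.data[:, self.valid].sum(axis=1)

    def feature_matrix(self) -> np.ndarray:
        """Values of valid cells, shape (n_valid, n_features), row-major cell order."""
        return self.data[:, self.valid].T.copy()

    def grid(self, name: str) -> Grid:
        i = self.index(name)
        return Grid(self.data[i], self.valid, self.cell_size, self.origin, name)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None

    def group_members(self, group: str) -> list[str]:
        return [n for n, g in zip(self.names, self.groups) if g == group]

    def subset(self, names: list[str]) -> "FeatureStack":
        idx = [self.index(n) for n in names]
        return FeatureStack(
            self.data[idx],
            [self.names[i] for i in idx],
            [self.groups[i] for i in idx],
            self.weights[idx],
            self.valid,
            self.cell_size,
            self.origin,
        )

    def with_weights(self, weights: np.ndarray) -> "FeatureStack":
        return FeatureStack(
            self.data, list(self.names), list(self.groups),
            np.asarray(weights, dtype=float), self.valid,
            self.cell_size, self.origin,
        )

    @classmethod
    def from_grids(
        cls,
        grids: list[Grid],
        names: list[str] | None = None,
        groups: list[str] | None = None,
        weights: np.ndarray | None = None,
    ) -> "FeatureStack":
        if not grids:
            raise GridError("empty stack")
        _check_coregistered(grids)
        names = names or [g.name or f"feature_{i}" for i, g in enumerate(grids)]
        groups = groups or ["feature"] * len(grids)
        if weights is None:
            weights = np.ones(len(grids))
        data = np.stack([g.values.astype(float) for g in grids])
        g0 = grids[0]
        return cls(data, list(names), list(groups), np.asarray(weights, float),
                   g0.valid, g0.cell_size, g0.origin)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_ascii(grid: Grid, path: str | Path) -> None:
    """Write an ESRI ASCII grid; valid values at full (round-trip) precision."""
    nr, nc = grid.shape
    x0, y0 = grid.origin
    vals = np.where(grid.valid, grid.values.astype(float), NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {(y0 - nr * grid.cell_size)!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for row in vals:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def read_ascii(path: str | Path, name: str = "") -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise GridError(f"{path}: missing header field {req}")
    nr, nc = int(header["nrows"]), int(header["ncols"])
    values = np.array(rows, dtype=float)
    if values.shape != (nr, nc):
        raise GridError(f"{path}: data shape {values.shape} != header ({nr}, {nc})")
    nod = header.get("nodata_value", NODATA)
    valid = values != nod
    cs = header["cellsize"]
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0) + nr * cs
    return Grid(values, valid, cs, (x0, y0), name or path.stem)


def write_geotiff(grid: Grid, path: str | Path) -> None:
    import tifffile

    x0, y0 = grid.origin
    vals = np.where(grid.valid, grid.values.astype(float), NODATA)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{NODATA:g}"),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path: str | Path, name: str = "") -> Grid:
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        cs = 1.0
        origin = (0.0, 0.0)
        nod = NODATA
        if _TAG_PIXEL_SCALE in tags:
            cs = float(tags[_TAG_PIXEL_SCALE].value[0])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        if _TAG_GDAL_NODATA in tags:
            nod = float(tags[_TAG_GDAL_NODATA].value)
    valid = ~np.isclose(values, nod)
    return Grid(values, valid, cs, origin, name or path.stem)


def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> None:
    fmt = format or _guess_format(path)
    if fmt == "ascii":
        write_ascii(grid, path)
    elif fmt == "geotiff":
        write_geotiff(grid, path)
    else:
        raise GridError(f"unknown format {fmt!r}")


def read_grid(path: str | Path, format: str | None = None, name: str = "") -> Grid:
    fmt = format or _guess_format(path)
    if fmt == "ascii":
        return read_ascii(path, name)
    if fmt == "geotiff":
        return read_geotiff(path, name)
    raise GridError(f"unknown format {fmt!r}")


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".asc", ".txt"):
        return "ascii"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    raise GridError(f"cannot guess format from suffix {suffix!r}")


def write_stack(stack: FeatureStack, directory: str | Path,
                format: str = "ascii") -> Path:
    """Write every layer plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if format == "ascii" else ".tif"
    entries = []
    for i, name in enumerate(stack.names):
        fname = f"{name}{ext}"
        write_grid(stack.grid(name), directory / fname, format)
        entries.append({
            "path": fname,
            "name": name,
            "group": stack.groups[i],
            "weight": float(stack.weights[i]),
        })
    manifest = directory / "stack.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"format": format, "layers": entries}, fh, sort_keys=False)
    return manifest


def read_stack(manifest_path: str | Path) -> FeatureStack:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    fmt = manifest.get("format", "ascii")
    grids, names, groups, weights = [], [], [], []
    for entry in manifest["layers"]:
        grids.append(read_grid(manifest_path.parent / entry["path"], fmt))
        names.append(entry["name"])
        groups.append(entry.get("group", "feature"))
        weights.append(float(entry.get("weight", 1.0)))
    return FeatureStack.from_grids(grids, names, groups, np.array(weights))


# ---------------------------------------------------------------------------
# Data preparation: fractional aggregation, resampling, class exclusion
# ---------------------------------------------------------------------------

def aggregate_fractional(
    fine: Grid,
    factor: int,
    labels: dict[int, str] | None = None,
    group: str = "habitat",
) -> FeatureStack:
    """Aggregate a fine categorical grid to fractional-cover layers.

    Each coarse cell covers a ``factor x factor`` block of fine cells; the
    layer for class ``c`` holds the fraction of *valid* fine cells in the
    block carrying ``c``.  Where the block is fully valid the fractions sum
    to 1; blocks with no valid fine cell become nodata.  Class area is
    conserved exactly because the fractions are ratios of integer counts.
    """
    if not fine.is_categorical:
        raise GridError("aggregate_fractional requires a categorical grid")
    if factor < 1:
        raise GridError("factor must be >= 1")
    nr, nc = fine.shape
    pad_r = (-nr) % factor
    pad_c = (-nc) % factor
    vals = fine.values
    valid = fine.valid
    if pad_r or pad_c:
        vals = np.pad(vals, ((0, pad_r), (0, pad_c)), constant_values=0)
        valid = np.pad(valid, ((0, pad_r), (0, pad_c)), constant_values=False)
    NR, NC = vals.shape[0] // factor, vals.shape[1] // factor
    blocks_v = vals.reshape(NR, factor, NC, factor)
    blocks_m = valid.reshape(NR, factor, NC, factor)
    classes = np.unique(fine.values[fine.valid])
    if classes.size == 0:
        raise GridError("no valid cells / empty class set")
    valid_counts = blocks_m.sum(axis=(1, 3))
    coarse_valid = valid_counts > 0
    layers = []
    names = []
    for c in classes:
        counts = ((blocks_v == c) & blocks_m).sum(axis=(1, 3))
        frac = np.zeros((NR, NC))
        np.divide(counts, valid_counts, out=frac, where=coarse_valid)
        layers.append(frac)
        names.append(labels[int(c)] if labels else f"class_{int(c)}")
    return FeatureStack(
        np.stack(layers),
        names,
        [group] * len(names),
        np.ones(len(names)),
        coarse_valid,
        fine.cell_size * factor,
        fine.origin,
    )


def resample_to_grid(
    coarse: Grid, target_cell_size: float, method: str = "bilinear"
) -> Grid:
    """Refine a layer to a finer cell size by an integer factor.

    Values are treated as intensive quantities (e.g. occurrence
    probabilities): a constant layer stays constant and the mean is
    approximately preserved; the relative change of the mean over valid
    cells is logged.  ``method`` is ``"bilinear"`` (cell-centre aligned)
    or ``"nearest"`` (block replication).
    """
    ratio = coarse.cell_size / target_cell_size
    factor = int(round(ratio))
    if factor < 1 or not np.isclose(ratio, factor):
        raise GridError(
            f"target cell size {target_cell_size} is not an integer refinement "
            f"of {coarse.cell_size}"
        )
    nr, nc = coarse.shape
    if method == "nearest":
        out = np.repeat(np.repeat(coarse.values.astype(float), factor, 0), factor, 1)
    elif method == "bilinear":
        # fine cell centres in coarse index coordinates
        rows = (np.arange(nr * factor) + 0.5) / factor - 0.5
        cols = (np.arange(nc * factor) + 0.5) / factor - 0.5
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        src = coarse.values.astype(float)
        if not coarse.valid.all():
            # fill nodata with nearest valid value so interpolation does not bleed
            idx = ndimage.distance_transform_edt(
                ~coarse.valid, return_distances=False, return_indices=True
            )
            src = src[tuple(idx)]
        out = ndimage.map_coordinates(src, [rr, cc], order=1, mode="nearest")
    else:
        raise GridError(f"unknown resampling method {method!r}")
    valid = np.repeat(np.repeat(coarse.valid, factor, 0), factor, 1)
    result = Grid(out, valid, target_cell_size, coarse.origin, coarse.name)
    old_mean = coarse.values[coarse.valid].mean() if coarse.valid.any() else 0.0
    new_mean = out[valid].mean() if valid.any() else 0.0
    if old_mean != 0:
        log.info(
            "resample %s: relative mean change %.3e",
            coarse.name or "<layer>", (new_mean - old_mean) / old_mean,
        )
    return result


def exclude_classes(
    stack: FeatureStack, class_labels: list[str], drop: bool = False
) -> FeatureStack:
    """Mark (or drop) built-up / excluded classes.

    By default the named layers are retained and re-labelled group
    ``"builtup"`` so that the prioritizer can give them a cumulative
    negative weight; with ``drop=True`` they are removed from the stack.
    """
    unknown = [c for c in class_labels if c not in stack.names]
    if unknown:
        raise KeyError(f"unknown class labels: {unknown}")
    if not class_labels:
        return stack
    if drop:
        keep = [n for n in stack.names if n not in class_labels]
        if not keep:
            raise GridError("cannot drop every layer of a stack")
        return stack.subset(keep)
    groups = [
        "builtup" if n in class_labels else g
        for n, g in zip(stack.names, stack.groups)
    ]
    return FeatureStack(
        stack.data, list(stack.names), groups, stack.weights.copy(),
        stack.valid, stack.cell_size, stack.origin,
    )
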