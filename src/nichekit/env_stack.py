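"""Environmental raster stacks: GeoTIFF I/O, alignment, resampling, collinearity screening.

The modelling space is an :class:`EnvStack` — a set of named predictor layers on one
shared grid with one shared validity mask.  Rasters are read from and written to
single-band GeoTIFF files; the georeferencing tags (pixel scale, tiepoint, EPSG code,
nodata) are handled directly on top of :mod:`tifffile`.

Conventions used everywhere in the package:

* row 0 is the northernmost row; the grid origin is the **outer** corner of cell
  (0, 0), i.e. the top-left (min-x, max-y) corner of the extent;
* cell (row, col) carries the coordinates of its center;
* extents are half-open: a point on the right/bottom edge is outside the grid.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import AlignmentError, InsufficientDataError, ResolutionError

logger = logging.getLogger(__name__)

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024        # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025       # 1 = PixelIsArea
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072

_GEOGRAPHIC_CRS_RE = re.compile(r"^(EPSG:4326|WGS ?84|CRS84|GEOGRAPHIC)$", re.IGNORECASE)

#: kilometres per degree of latitude (spherical mean radius); used for
#: cell areas on geographic grids.
KM_PER_DEGREE = 111.32

#: default target resolution (metres) used when standardizing projected stacks.
DEFAULT_CELL_SIZE_M = 250.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    cell_size
        Square cell edge in map units (metres for projected CRSs, degrees for
        geographic ones).
    origin_x, origin_y
        Coordinates of the outer (top-left) corner of cell (0, 0).
    crs_id
        Textual CRS identifier, e.g. ``"EPSG:32652"`` or ``"EPSG:4326"``.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_id: str = "EPSG:32652"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_geographic(self) -> bool:
        """True when coordinates are lon/lat degrees."""
        return bool(_GEOGRAPHIC_CRS_RE.match(self.crs_id.strip()))

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of cell centers."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing the points (may be off-grid)."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def matches(self, other: "GridSpec", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=rtol)
            and math.isclose(self.origin_x, other.origin_x, rel_tol=rtol, abs_tol=1e-6 * self.cell_size)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=rtol, abs_tol=1e-6 * self.cell_size)
            and self.crs_id.strip().upper() == other.crs_id.strip().upper()
        )


@dataclass
class EnvStack:
    """Aligned multi-variable raster stack with a single shared mask.

    ``values`` has shape ``(n_vars, n_rows, n_cols)``; masked-out cells hold NaN,
    masked-in cells are always finite.
    """

    grid: GridSpec
    variables: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.variables), self.grid.n_rows, self.grid.n_cols):
            raise ValueError("values shape does not match variables/grid")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not np.all(np.isfinite(self.values[:, self.mask])):
            raise ValueError("non-finite values on masked-in cells")
        self.values[:, ~self.mask] = np.nan

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.variables.index(name)]

    def subset(self, names: Sequence[str]) -> "EnvStack":
        idx = [self.variables.index(n) for n in names]
        return EnvStack(self.grid, list(names), self.values[idx].copy(), self.mask.copy())

    def table_at_cells(self, rows: np.ndarray, cols: np.ndarray,
                       variables: Sequence[str] | None = None) -> np.ndarray:
        """Predictor matrix (n_points, n_vars) extracted at cell indices."""
        names = list(variables) if variables is not None else self.variables
        idx = [self.variables.index(n) for n in names]
        return self.values[idx][:, rows, cols].T


@dataclass
class CollinearityReport:
    """Outcome of pairwise-|r| screening.

    ``dropped`` records, for each excluded variable, the partner and the signed
    Pearson r of the violating pair that triggered the exclusion.
    """

    retained: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = 0.7

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "status": "retained", "partner": "", "r": np.nan}
                for v in self.retained]
        rows += [{"variable": v, "status": "dropped", "partner": p, "r": r}
                 for v, p, r in self.dropped]
        return pd.DataFrame(rows, columns=["variable", "status", "partner", "r"])


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _crs_to_geokeys(crs_id: str) -> tuple:
    m = re.match(r"EPSG:(\d+)$", crs_id.strip(), re.IGNORECASE)
    epsg = int(m.group(1)) if m else 0
    geographic = _GEOGRAPHIC_CRS_RE.match(crs_id.strip()) is not None
    keys = [(_KEY_MODEL_TYPE, 0, 1, 2 if geographic else 1), (_KEY_RASTER_TYPE, 0, 1, 1)]
    if epsg:
        keys.append((_KEY_GEOGRAPHIC_CS if geographic else _KEY_PROJECTED_CS, 0, 1, epsg))
    flat: list[int] = [1, 1, 0, len(keys)]
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def _geokeys_to_crs(flat: Sequence[int] | None) -> str:
    if not flat or len(flat) < 4:
        return "UNKNOWN"
    n_keys = flat[3]
    keys = {flat[4 + 4 * i]: flat[7 + 4 * i] for i in range(n_keys) if 7 + 4 * i < len(flat)}
    for key in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
        if keys.get(key):
            return f"EPSG:{keys[key]}"
    return "GEOGRAPHIC" if keys.get(_KEY_MODEL_TYPE) == 2 else "UNKNOWN"


def write_geotiff(path: str | Path, values: np.ndarray, grid: GridSpec,
                  nodata: float | None = None, dtype=None) -> None:
    """Write one layer as a single-band GeoTIFF.

    NaNs in a float layer are replaced by ``nodata`` (default −9999) before
    writing; the nodata value is recorded in the GDAL nodata tag.
    """
    arr = np.asarray(values)
    if arr.shape != grid.shape:
        raise ValueError("layer shape does not match grid")
    if dtype is not None:
        arr = arr.astype(dtype)
    if np.issubdtype(arr.dtype, np.floating):
        if nodata is None:
            nodata = -9999.0
        arr = np.where(np.isnan(arr), nodata, arr)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0), True),
        (_TAG_GEO_KEYS, "H", len(_crs_to_geokeys(grid.crs_id)),
         _crs_to_geokeys(grid.crs_id), True),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(float(nodata)), True))
    tifffile.imwrite(path, arr, extratags=extratags)


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridSpec, float | None]:
    """Read a single-band GeoTIFF -> (values, grid, nodata)."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise OSError(f"{path}: expected a single-band raster, got shape {arr.shape}")
        tags = page.tags
        try:
            scale = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise OSError(f"{path}: missing georeferencing tags") from exc
        if not math.isclose(scale[0], scale[1], rel_tol=1e-9):
            raise OSError(f"{path}: non-square cells not supported")
        # tiepoint maps raster (i, j) -> model (x, y); shift to the (0,0) corner
        origin_x = tie[3] - tie[0] * scale[0]
        origin_y = tie[4] + tie[1] * scale[1]
        crs_id = _geokeys_to_crs(tags[_TAG_GEO_KEYS].value if _TAG_GEO_KEYS in tags else None)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    grid = GridSpec(arr.shape[0], arr.shape[1], float(scale[0]), origin_x, origin_y, crs_id)
    return arr, grid, nodata


def read_stack(paths: Iterable[str | Path]) -> EnvStack:
    """Read aligned single-band rasters into one stack.

    Variable names are the file stems.  The stack mask is the intersection of the
    per-layer valid masks (union of nodata regions is masked out).  A layer whose
    grid differs from the first layer's raises :class:`AlignmentError` naming it.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster paths given")
    layers, grid = [], None
    mask = None
    for p in paths:
        arr, g, nodata = read_geotiff(p)
        if grid is None:
            grid = g
        elif not grid.matches(g):
            raise AlignmentError(f"layer '{p.stem}' does not align with '{paths[0].stem}'")
        arr = np.asarray(arr, dtype=float)
        valid = np.isfinite(arr)
        if nodata is not None:
            valid &= arr != nodata
        mask = valid if mask is None else (mask & valid)
        layers.append(arr)
    values = np.stack(layers)
    values[:, ~mask] = np.nan
    return EnvStack(grid, [p.stem for p in paths], values, mask)


def write_stack(stack: EnvStack, out_dir: str | Path, nodata: float = -9999.0) -> list[Path]:
    """Write every layer of a stack as ``<out_dir>/<variable>.tif``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, name in enumerate(stack.variables):
        path = out_dir / f"{name}.tif"
        write_geotiff(path, stack.values[i].astype(np.float32), stack.grid, nodata=nodata)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(stack: EnvStack, target_cell_size: float,
                method: str = "mean_aggregate") -> EnvStack:
    """Change the stack resolution.

    ``mean_aggregate`` coarsens by an integer factor, averaging the valid cells of
    each window (windows with no valid cell are masked out).  ``nearest`` refines
    by an integer factor, replicating cell values.  Grid dimensions must be
    divisible by the aggregation factor.
    """
    cur = stack.grid.cell_size
    if math.isclose(target_cell_size, cur, rel_tol=1e-9):
        return EnvStack(stack.grid, list(stack.variables), stack.values.copy(), stack.mask.copy())
    if method == "mean_aggregate":
        factor = target_cell_size / cur
        k = round(factor)
        if k < 1 or not math.isclose(factor, k, rel_tol=1e-9):
            raise ResolutionError(
                f"target {target_cell_size} is not an integer multiple of {cur}")
        if stack.grid.n_rows % k or stack.grid.n_cols % k:
            raise ResolutionError(f"grid shape {stack.grid.shape} not divisible by {k}")
        nr, nc = stack.grid.n_rows // k, stack.grid.n_cols // k
        m = stack.mask.reshape(nr, k, nc, k)
        counts = m.sum(axis=(1, 3))
        filled = np.where(stack.mask, stack.values, 0.0)
        sums = filled.reshape(stack.n_vars, nr, k, nc, k).sum(axis=(2, 4))
        new_mask = counts > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(new_mask, sums / np.maximum(counts, 1), np.nan)
    elif method == "nearest":
        factor = cur / target_cell_size
        k = round(factor)
        if k < 1 or not math.isclose(factor, k, rel_tol=1e-9):
            raise ResolutionError(
                f"target {target_cell_size} is not an integer divisor of {cur}")
        vals = np.repeat(np.repeat(stack.values, k, axis=1), k, axis=2)
        new_mask = np.repeat(np.repeat(stack.mask, k, axis=0), k, axis=1)
        nr, nc = new_mask.shape
    else:
        raise ValueError(f"unknown method '{method}'")
    grid = replace(stack.grid, n_rows=nr, n_cols=nc, cell_size=float(target_cell_size))
    return EnvStack(grid, list(stack.variables), vals, new_mask)


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def collinearity_filter(stack: EnvStack, threshold: float = 0.7,
                        priority: Sequence[str] | None = None) -> CollinearityReport:
    """Greedy pairwise Pearson screening at |r| >= ``threshold``.

    Violating pairs are visited in decreasing |r|; within a pair the variable with
    the higher mean absolute correlation to all other variables is dropped (ties
    drop the one later in ``priority``, alphabetical by default).  The retained set
    contains no pair with |r| >= threshold, and re-filtering it drops nothing.
    """
    if stack.n_vars < 2:
        raise InsufficientDataError("need at least 2 variables to screen")
    valid = stack.mask
    if valid.sum() < 2:
        raise InsufficientDataError("need at least 2 valid cells to correlate")
    X = stack.values[:, valid]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance layers correlate with nothing
    np.fill_diagonal(corr, 1.0)

    names = stack.variables
    order = list(priority) if priority is not None else sorted(names)
    rank = {n: order.index(n) if n in order else len(order) for n in names}
    n = len(names)
    abs_corr = np.abs(corr)
    mean_abs = (abs_corr.sum(axis=1) - 1.0) / (n - 1)

    pairs = [(abs_corr[i, j], i, j) for i in range(n) for j in range(i + 1, n)
             if abs_corr[i, j] >= threshold]
    pairs.sort(key=lambda t: (-t[0], names[t[1]], names[t[2]]))

    dropped: dict[str, tuple[str, float]] = {}
    for _, i, j in pairs:
        ni, nj = names[i], names[j]
        if ni in dropped or nj in dropped:
            continue
        if mean_abs[i] > mean_abs[j]:
            victim, partner = ni, nj
        elif mean_abs[j] > mean_abs[i]:
            victim, partner = nj, ni
        else:
            victim, partner = (ni, nj) if rank[ni] > rank[nj] else (nj, ni)
        dropped[victim] = (partner, float(corr[i, j]))
        logger.info("collinearity: dropping %s (r=%.3f with %s)", victim, corr[i, j], partner)

    retained = [nm for nm in names if nm not in dropped]
    report = CollinearityReport(
        retained=retained,
        dropped=[(v, p, r) for v, (p, r) in dropped.items()],
        threshold=threshold,
    )
    return report
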