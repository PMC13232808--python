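"""Projection and downstream change statistics.

Ensembles are projected onto scenario stacks to give continuous suitability
maps, thresholded into binary range maps at the TSS-maximizing cutoff, and
summarized as: range-change index (colonized minus lost area over baseline
area, as a percentage), Schoener's D niche overlap between species, median
centroid positions (longitude, latitude, elevation) of the suitable range,
per-cell species richness and its change, and occurrence frequencies across
categorical zones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .env_stack import KM_PER_DEGREE, EnvStack, GridSpec
from .ensemble import EnsembleModel, ensemble_predict
from .errors import (AlignmentError, EmptyRangeError, SchemaError,
                     UndefinedOverlapError, UndefinedRCIError)
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)


@dataclass
class SuitabilityMap:
    """Continuous [0, 1] habitat suitability on a grid."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        v = self.values[self.mask]
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")
        self.values[~self.mask] = np.nan


@dataclass
class BinaryMap:
    """Thresholded {0, 1} range map."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray
    threshold_used: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        v = self.values[self.mask]
        if not np.isin(v, (0, 1)).all():
            raise ValueError("binary map values must be 0/1 on masked-in cells")
        self.values = np.where(self.mask, self.values.astype(np.uint8), 0).astype(np.uint8)

    @property
    def suitable(self) -> np.ndarray:
        return self.mask & (self.values == 1)


def project(ens: EnsembleModel, stack: EnvStack, kind: str = "EMwmean",
            provenance: dict | None = None) -> SuitabilityMap:
    """Predict the ensemble on every masked-in cell of a stack."""
    missing = [v for v in ens.variables if v not in stack.variables]
    if missing:
        raise SchemaError(f"stack is missing training variables: {missing}")
    rows, cols = np.nonzero(stack.mask)
    X = stack.table_at_cells(rows, cols, ens.variables)
    pred = ensemble_predict(ens, X, kind=kind)
    values = np.full(stack.grid.shape, np.nan)
    values[rows, cols] = pred
    prov = {"species": ens.species, "ensemble": kind}
    prov.update(provenance or {})
    return SuitabilityMap(stack.grid, values, stack.mask.copy(), prov)


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Suitable (1) where suitability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    vals = np.where(smap.mask, (smap.values >= threshold).astype(np.uint8), 0)
    return BinaryMap(smap.grid, vals, smap.mask.copy(), threshold_used=threshold,
                     provenance=dict(smap.provenance))


def average_suitability(maps: Sequence[SuitabilityMap]) -> SuitabilityMap:
    """Mean of continuous maps across periods (before thresholding)."""
    first = maps[0]
    for m in maps[1:]:
        if not first.grid.matches(m.grid) or not np.array_equal(first.mask, m.mask):
            raise AlignmentError("period maps must share grid and mask")
    vals = np.nanmean(np.stack([m.values for m in maps]), axis=0)
    prov = dict(first.provenance)
    prov["period"] = "mean_of_%d" % len(maps)
    return SuitabilityMap(first.grid, vals, first.mask.copy(), prov)


def majority_binary(maps: Sequence[BinaryMap]) -> BinaryMap:
    """Alternative period summary: suitable where most period binaries agree."""
    first = maps[0]
    votes = np.stack([m.values for m in maps]).sum(axis=0)
    vals = (votes * 2 > len(maps)).astype(np.uint8)
    return BinaryMap(first.grid, vals, first.mask.copy(),
                     threshold_used=float("nan"),
                     provenance={**first.provenance, "period": "majority"})


# ---------------------------------------------------------------------------
# Areas and range change
# ---------------------------------------------------------------------------

def cell_area(grid: GridSpec, row: int | np.ndarray) -> float | np.ndarray:
    """Cell area in km².

    Projected grids (cell size in metres): constant ``(cell/1000)²``.  Geographic
    grids (cell size in degrees): ``(cell · 111.32 km)² · cos(latitude)`` of the
    row center.
    """
    if grid.is_geographic:
        _, lat = grid.cell_center(np.asarray(row), 0)
        a = (grid.cell_size * KM_PER_DEGREE) ** 2 * np.cos(np.radians(lat))
        return float(a) if np.isscalar(row) or np.ndim(row) == 0 else a
    a = (grid.cell_size / 1000.0) ** 2
    return a if np.isscalar(row) or np.ndim(row) == 0 else np.full(np.shape(row), a)


@dataclass
class ChangeSummary:
    """Areas (km²) of colonization/extinction/stability and the range change index."""

    s_colonization: float
    s_extinction: float
    s_present: float
    s_stable: float
    rci: float

    def to_dict(self) -> dict:
        return {"s_colonization_km2": self.s_colonization,
                "s_extinction_km2": self.s_extinction,
                "s_present_km2": self.s_present,
                "s_stable_km2": self.s_stable,
                "rci": self.rci}


def range_change(baseline: BinaryMap, future: BinaryMap) -> ChangeSummary:
    """Range change index: (colonized − lost) / baseline area × 100.

    −100 means complete loss of the baseline range within the study area; 0 means
    gains exactly offset losses.
    """
    if not baseline.grid.matches(future.grid) or not np.array_equal(baseline.mask, future.mask):
        raise AlignmentError("baseline and future maps must share grid and mask")
    b, f = baseline.suitable, future.suitable
    rows_b = np.nonzero(b)[0]
    if rows_b.size == 0:
        raise UndefinedRCIError("baseline has no suitable cells; RCI undefined")
    grid = baseline.grid
    s_present = float(np.sum(cell_area(grid, np.nonzero(b)[0])))
    col = f & ~b
    ext = b & ~f
    stable = b & f
    s_col = float(np.sum(cell_area(grid, np.nonzero(col)[0]))) if col.any() else 0.0
    s_ext = float(np.sum(cell_area(grid, np.nonzero(ext)[0]))) if ext.any() else 0.0
    s_stab = float(np.sum(cell_area(grid, np.nonzero(stable)[0]))) if stable.any() else 0.0
    rci = (s_col - s_ext) / s_present * 100.0
    return ChangeSummary(s_col, s_ext, s_present, s_stab, rci)


# ---------------------------------------------------------------------------
# Niche overlap
# ---------------------------------------------------------------------------

def schoener_d(a: SuitabilityMap | BinaryMap, b: SuitabilityMap | BinaryMap,
               mode: str = "binary") -> float:
    """Schoener's D between two maps: 1 − ½ Σ|pᵢ − qᵢ| after normalizing each
    map to sum 1 over masked-in cells.  1 = identical, 0 = disjoint."""
    if mode not in ("binary", "continuous"):
        raise ValueError("mode must be 'binary' or 'continuous'")
    if not a.grid.matches(b.grid) or not np.array_equal(a.mask, b.mask):
        raise AlignmentError("overlap maps must share grid and mask")
    pa = np.asarray(a.values, dtype=float)[a.mask]
    pb = np.asarray(b.values, dtype=float)[b.mask]
    ta, tb = np.nansum(pa), np.nansum(pb)
    if ta <= 0 or tb <= 0:
        raise UndefinedOverlapError("a zero-total map cannot be normalized")
    return float(1.0 - 0.5 * np.sum(np.abs(pa / ta - pb / tb)))


@dataclass
class OverlapMatrix:
    """Symmetric pairwise Schoener's D among species."""

    species: list[str]
    d: np.ndarray
    mode: str = "binary"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.species, columns=self.species)

    def pair(self, sp1: str, sp2: str) -> float:
        return float(self.d[self.species.index(sp1), self.species.index(sp2)])


def overlap_matrix(maps: Mapping[str, SuitabilityMap | BinaryMap],
                   mode: str = "binary") -> OverlapMatrix:
    """Pairwise D among species maps.

    A map with zero total (e.g. complete projected habitat loss) has no
    normalizable distribution; its pairs, and its diagonal, are NaN rather
    than aborting the whole matrix.
    """
    species = list(maps)
    n = len(species)
    zero = [float(np.nansum(np.asarray(maps[sp].values, float)[maps[sp].mask])) <= 0
            for sp in species]
    for sp, z in zip(species, zero):
        if z:
            logger.warning("overlap: '%s' has a zero-total map; its D values are NaN", sp)
    d = np.eye(n)
    for i in range(n):
        if zero[i]:
            d[i, i] = np.nan
        for j in range(i + 1, n):
            if zero[i] or zero[j]:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = schoener_d(maps[species[i]], maps[species[j]], mode)
    return OverlapMatrix(species, d, mode)


def relative_overlap_change(d_base: float, d_future: float) -> float:
    """Percent change of Schoener's D relative to baseline, to one decimal."""
    if d_base <= 0:
        raise UndefinedOverlapError("relative change undefined for zero baseline D")
    return round(100.0 * (d_future - d_base) / d_base, 1)


# ---------------------------------------------------------------------------
# Centroids
# ---------------------------------------------------------------------------

@dataclass
class CentroidRecord:
    """Median position of the suitable range (outlier-robust centroid)."""

    median_lon: float
    median_lat: float
    median_elev: float | None
    n_cells: int


def centroid(bmap: BinaryMap, elevation: EnvStack | np.ndarray | None = None) -> CentroidRecord:
    """Component-wise medians over suitable cell centers (and their elevations).

    Even counts use the midpoint of the two central order statistics (numpy's
    median convention).
    """
    rows, cols = np.nonzero(bmap.suitable)
    if rows.size == 0:
        raise EmptyRangeError("no suitable cells; centroid undefined")
    x, y = bmap.grid.cell_center(rows, cols)
    med_elev = None
    if elevation is not None:
        if isinstance(elevation, EnvStack):
            if not elevation.grid.matches(bmap.grid):
                raise AlignmentError("elevation grid does not match the map")
            elev = elevation.values[0]
        else:
            elev = np.asarray(elevation, dtype=float)
        vals = elev[rows, cols]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            med_elev = float(np.median(vals))
    return CentroidRecord(float(np.median(x)), float(np.median(y)), med_elev,
                          int(rows.size))


def genus_centroid(maps: Sequence[BinaryMap],
                   elevation: EnvStack | np.ndarray | None = None,
                   method: str = "union") -> CentroidRecord:
    """Genus-level centroid: of the union of suitable cells (``union``), or the
    component-wise mean of per-species centroids (``mean``)."""
    if method == "union":
        first = maps[0]
        union = np.zeros(first.grid.shape, dtype=np.uint8)
        for m in maps:
            if not first.grid.matches(m.grid):
                raise AlignmentError("species maps must share one grid")
            union |= m.suitable.astype(np.uint8)
        bmap = BinaryMap(first.grid, union, first.mask.copy())
        return centroid(bmap, elevation)
    if method == "mean":
        recs = [centroid(m, elevation) for m in maps]
        elevs = [r.median_elev for r in recs if r.median_elev is not None]
        return CentroidRecord(float(np.mean([r.median_lon for r in recs])),
                              float(np.mean([r.median_lat for r in recs])),
                              float(np.mean(elevs)) if elevs else None,
                              int(sum(r.n_cells for r in recs)))
    raise ValueError("method must be 'union' or 'mean'")


# ---------------------------------------------------------------------------
# Richness and zones
# ---------------------------------------------------------------------------

@dataclass
class RichnessMap:
    """Per-cell species richness (count of suitable species) and its normalization."""

    grid: GridSpec
    sr: np.ndarray
    n_species: int
    mask: np.ndarray

    @property
    def sr_norm(self) -> np.ndarray:
        return np.where(self.mask, self.sr / self.n_species, np.nan)


def richness(maps: Sequence[BinaryMap]) -> RichnessMap:
    """Per-cell sum of species binary maps."""
    first = maps[0]
    for m in maps[1:]:
        if not first.grid.matches(m.grid) or not np.array_equal(first.mask, m.mask):
            raise AlignmentError("richness inputs must share grid and mask")
    sr = np.stack([m.suitable.astype(np.int16) for m in maps]).sum(axis=0)
    return RichnessMap(first.grid, sr, len(maps), first.mask.copy())


def richness_delta(future: RichnessMap, baseline: RichnessMap) -> np.ndarray:
    """ΔSR = future − baseline richness, per cell (masked cells are 0)."""
    if not future.grid.matches(baseline.grid):
        raise AlignmentError("richness maps must share one grid")
    return np.where(future.mask & baseline.mask,
                    future.sr.astype(np.int16) - baseline.sr.astype(np.int16), 0)


def zone_frequency(occ: OccurrenceSet, zones: EnvStack) -> pd.DataFrame:
    """Occurrence counts and percentages per categorical-zone label.

    Percentages sum to 100 over points assigned to a zone; points off the zone
    grid or on masked zone cells are reported under label ``"<off-zone>"`` with
    a blank percentage.
    """
    grid = zones.grid
    zvals = zones.values[0]
    row, col = grid.point_to_cell(occ.points[:, 0], occ.points[:, 1])
    inside = grid.contains(row, col)
    assigned = np.zeros(len(occ), dtype=bool)
    labels = np.full(len(occ), np.nan)
    r, c = row[inside], col[inside]
    valid = zones.mask[r, c]
    idx = np.flatnonzero(inside)[valid]
    labels[idx] = zvals[r[valid], c[valid]]
    assigned[idx] = True

    rows = []
    n_assigned = int(assigned.sum())
    if n_assigned:
        uniq, counts = np.unique(labels[assigned], return_counts=True)
        for z, k in zip(uniq, counts):
            rows.append({"zone": int(z) if float(z).is_integer() else float(z),
                         "count": int(k),
                         "percent": round(100.0 * k / n_assigned, 1)})
    n_off = len(occ) - n_assigned
    if n_off:
        rows.append({"zone": "<off-zone>", "count": n_off, "percent": np.nan})
    return pd.DataFrame(rows, columns=["zone", "count", "percent"])
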