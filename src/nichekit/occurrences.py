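"""Occurrence formatting and pseudo-absence generation.

Presence records are snapped to the modelling grid, deduplicated to one record
per cell, optionally capped by random subsampling, and combined with randomly
placed pseudo-absence (background) cells into a presence/background modelling
table with class-balancing weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .env_stack import EnvStack, GridSpec
from .errors import EmptySetError, SamplingError

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE_CAP = 500
DEFAULT_N_PSEUDO_ABSENCES = 1000


@dataclass
class OccurrenceSet:
    """Point records for one species.

    ``points`` is an (n, 2) array of (x, y) — lon/lat on geographic grids.
    ``cell_indices`` is an (n, 2) array of (row, col) once snapped to a grid,
    or None for raw records.
    """

    species: str
    points: np.ndarray
    cell_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.cell_indices is not None:
            self.cell_indices = np.atleast_2d(np.asarray(self.cell_indices, dtype=int))

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_csv(cls, path: str | Path, species: str | None = None) -> "dict[str, OccurrenceSet] | OccurrenceSet":
        """Read an occurrence CSV with columns ``species, lon, lat``.

        With ``species`` given, returns that one set; otherwise a dict keyed by
        species name.
        """
        df = pd.read_csv(path)
        missing = {"species", "lon", "lat"} - set(df.columns)
        if missing:
            raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
        if species is not None:
            sub = df[df["species"] == species]
            return cls(species, sub[["lon", "lat"]].to_numpy())
        return {sp: cls(sp, g[["lon", "lat"]].to_numpy())
                for sp, g in df.groupby("species", sort=True)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species,
                             "lon": self.points[:, 0], "lat": self.points[:, 1]})


def dedupe_to_grid(raw: OccurrenceSet, grid: GridSpec,
                   mask: np.ndarray | None = None) -> OccurrenceSet:
    """Snap records to the grid and keep one per cell (first in input order).

    Points outside the grid, or on masked-out cells when ``mask`` is given, are
    dropped and counted in the log.  An empty result raises
    :class:`EmptySetError`.  Retained points are moved to their cell centers so
    downstream extraction is exact; the operation is idempotent.
    """
    row, col = grid.point_to_cell(raw.points[:, 0], raw.points[:, 1])
    inside = grid.contains(row, col)
    n_off = int((~inside).sum())
    if mask is not None:
        on_valid = np.zeros(len(raw), dtype=bool)
        on_valid[inside] = mask[row[inside], col[inside]]
    else:
        on_valid = inside
    n_masked = int(inside.sum() - on_valid.sum())

    seen: set[tuple[int, int]] = set()
    keep = []
    for i in np.flatnonzero(on_valid):
        cell = (int(row[i]), int(col[i]))
        if cell not in seen:
            seen.add(cell)
            keep.append(i)
    n_dup = int(on_valid.sum()) - len(keep)
    logger.info("%s: formatted %d/%d records (%d off-grid, %d on masked cells, %d duplicates)",
                raw.species, len(keep), len(raw), n_off, n_masked, n_dup)
    if not keep:
        raise EmptySetError(f"{raw.species}: no records remain after grid formatting")
    keep = np.asarray(keep)
    cells = np.column_stack([row[keep], col[keep]])
    x, y = grid.cell_center(cells[:, 0], cells[:, 1])
    return OccurrenceSet(raw.species, np.column_stack([x, y]), cells)


def subsample(occ: OccurrenceSet, cap: int = DEFAULT_SUBSAMPLE_CAP,
              seed: int = 0) -> OccurrenceSet:
    """Uniform random cap on the number of records; identity when already within it."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(occ) <= cap:
        return occ
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(occ), size=cap, replace=False))
    cells = occ.cell_indices[idx] if occ.cell_indices is not None else None
    logger.info("%s: subsampled %d -> %d records", occ.species, len(occ), cap)
    return OccurrenceSet(occ.species, occ.points[idx], cells)


def sample_pseudo_absences(stack: EnvStack, presences: OccurrenceSet,
                           n: int = DEFAULT_N_PSEUDO_ABSENCES, seed: int = 0,
                           exclude_presence_cells: bool = True) -> OccurrenceSet:
    """Draw ``n`` background cells uniformly without replacement from the study area.

    Eligible cells are the masked-in cells of the stack, minus presence cells when
    ``exclude_presence_cells`` (the default, avoiding contradictory labels on a
    shared grid).  Points are placed at cell centers.
    """
    eligible = stack.mask.copy()
    if exclude_presence_cells and presences.cell_indices is not None:
        eligible[presences.cell_indices[:, 0], presences.cell_indices[:, 1]] = False
    rows, cols = np.nonzero(eligible)
    if len(rows) < n:
        raise SamplingError(
            f"only {len(rows)} eligible cells for {n} pseudo-absences "
            f"(short by {n - len(rows)})")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    cells = np.column_stack([rows[pick], cols[pick]])
    x, y = stack.grid.cell_center(cells[:, 0], cells[:, 1])
    return OccurrenceSet(presences.species, np.column_stack([x, y]), cells)


@dataclass
class ModelingTable:
    """Presence/background rows with predictor values, 0/1 label and weight."""

    frame: pd.DataFrame
    variables: list[str] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.variables].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def weights(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def build_modeling_table(stack: EnvStack, presences: OccurrenceSet,
                         absences: OccurrenceSet,
                         balance_classes: bool = True) -> ModelingTable:
    """Extract predictors at presence and pseudo-absence cells.

    With ``balance_classes`` (default) weights are scaled so the total presence
    weight equals the total absence weight (effective prevalence 0.5); absences
    carry weight 1.  Points on masked cells are dropped with a logged warning.
    """
    parts = []
    for occ, label in ((presences, 1), (absences, 0)):
        if occ.cell_indices is None:
            raise ValueError("occurrence sets must be snapped to the grid first")
        r, c = occ.cell_indices[:, 0], occ.cell_indices[:, 1]
        on = stack.mask[r, c]
        if not on.all():
            logger.warning("%s: dropping %d label-%d points on masked cells",
                           occ.species, int((~on).sum()), label)
        r, c = r[on], c[on]
        X = stack.table_at_cells(r, c)
        df = pd.DataFrame(X, columns=stack.variables)
        df["label"] = label
        df["lon"], df["lat"] = stack.grid.cell_center(r, c)
        df["row"], df["col"] = r, c
        parts.append(df)
    frame = pd.concat(parts, ignore_index=True)
    n_p = int((frame["label"] == 1).sum())
    n_a = int((frame["label"] == 0).sum())
    if n_p == 0 or n_a == 0:
        raise EmptySetError("modelling table needs both presences and absences")
    frame["weight"] = 1.0
    if balance_classes:
        frame.loc[frame["label"] == 1, "weight"] = n_a / n_p
    return ModelingTable(frame, list(stack.variables))
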