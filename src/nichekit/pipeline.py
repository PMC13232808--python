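"""Stage orchestration: screen -> fit -> project -> change -> overlap -> report.

Each stage reads its inputs from disk and writes its artifacts under the run's
output directory, so any stage can be re-run in isolation once its upstream
artifacts exist.  All stochastic steps take seeds derived from the master seed
by fixed tags, so two runs with the same configuration are identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import change as ch
from . import ensemble as ens_mod
from .config import RunConfig
from .env_stack import (EnvStack, collinearity_filter, read_geotiff, read_stack,
                        resample_to, write_geotiff)
from .errors import DependencyError
from .occurrences import (OccurrenceSet, build_modeling_table, dedupe_to_grid,
                          sample_pseudo_absences, subsample)

logger = logging.getLogger(__name__)

STAGES = ("screen", "fit", "project", "change", "overlap", "report")


def _tif_paths(directory: str | Path) -> list[Path]:
    paths = sorted(Path(directory).glob("*.tif"))
    if not paths:
        raise DependencyError(f"no GeoTIFF layers found under {directory}")
    return paths


def _out(cfg: RunConfig, *parts: str) -> Path:
    p = Path(cfg.output_dir).joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def _load_baseline(cfg: RunConfig, retained: list[str] | None = None) -> EnvStack:
    stack = read_stack(_tif_paths(cfg.baseline_dir))
    if cfg.resample_cell_size:
        stack = resample_to(stack, cfg.resample_cell_size)
    if retained is not None:
        stack = stack.subset(retained)
    return stack


def _load_scenario(cfg: RunConfig, label: str, retained: list[str] | None) -> EnvStack:
    stack = read_stack(_tif_paths(cfg.scenario_dirs[label]))
    if cfg.resample_cell_size:
        stack = resample_to(stack, cfg.resample_cell_size)
    if retained is not None:
        stack = stack.subset(retained)
    return stack


def _retained_variables(cfg: RunConfig) -> list[str]:
    path = _out(cfg, "screen", "collinearity.csv")
    if not path.exists():
        raise DependencyError("run the 'screen' stage first (collinearity.csv missing)")
    df = pd.read_csv(path)
    return df.loc[df["status"] == "retained", "variable"].tolist()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_screen(cfg: RunConfig) -> None:
    stack = _load_baseline(cfg)
    report = collinearity_filter(stack, threshold=cfg.collinearity_threshold)
    report.to_frame().to_csv(_out(cfg, "screen", "collinearity.csv"), index=False)
    logger.info("screen: retained %d/%d variables", len(report.retained), stack.n_vars)


def stage_fit(cfg: RunConfig) -> None:
    retained = _retained_variables(cfg)
    stack = _load_baseline(cfg, retained)
    occ_by_species = OccurrenceSet.from_csv(cfg.occurrences_csv)
    for sp, occ in occ_by_species.items():
        seed = ens_mod.derive_seed(cfg.master_seed, "fit", sp)
        occ = dedupe_to_grid(occ, stack.grid, stack.mask)
        occ = subsample(occ, cap=cfg.subsample_cap, seed=ens_mod.derive_seed(seed, "sub"))
        pa = sample_pseudo_absences(stack, occ, n=cfg.n_pseudo_absences,
                                    seed=ens_mod.derive_seed(seed, "pa"))
        table = build_modeling_table(stack, occ, pa)
        ensemble = ens_mod.build_ensemble(
            table, tags=tuple(cfg.learners), calib_frac=cfg.calib_frac,
            reps=cfg.reps, auc_gate=cfg.auc_gate, ci_alpha=cfg.ci_alpha,
            seed=seed, species=sp)
        ens_mod.metrics_frame(ensemble.members).to_csv(
            _out(cfg, "fit", sp, "metrics.csv"), index=False)
        ens_mod.importance_table(ensemble, table,
                                 seed=ens_mod.derive_seed(seed, "imp")).to_csv(
            _out(cfg, "fit", sp, "importance.csv"), index=False)
        manifest = ens_mod.save_ensemble(ensemble, _out(cfg, "fit", sp, "ensemble.pkl"))
        with open(_out(cfg, "fit", sp, "ensemble.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("fit %s: %d members retained, threshold %.3f",
                    sp, len(ensemble.members), ensemble.threshold)


def _species_dirs(cfg: RunConfig) -> list[Path]:
    fit_dir = Path(cfg.output_dir) / "fit"
    if not fit_dir.is_dir():
        raise DependencyError("run the 'fit' stage first (fit/ missing)")
    dirs = sorted(d for d in fit_dir.iterdir() if (d / "ensemble.pkl").exists())
    if not dirs:
        raise DependencyError("no fitted ensembles under fit/")
    return dirs


def _periods(cfg: RunConfig) -> list[str]:
    return ["baseline"] + sorted(cfg.scenario_dirs)


def stage_project(cfg: RunConfig) -> None:
    retained = _retained_variables(cfg)
    stacks = {"baseline": _load_baseline(cfg, retained)}
    for label in sorted(cfg.scenario_dirs):
        stacks[label] = _load_scenario(cfg, label, retained)
    for sp_dir in _species_dirs(cfg):
        sp = sp_dir.name
        ensemble = ens_mod.load_ensemble(sp_dir / "ensemble.pkl")
        for label, stack in stacks.items():
            smap = ch.project(ensemble, stack, provenance={"period": label})
            bmap = ch.binarize(smap, ensemble.threshold)
            write_geotiff(_out(cfg, "project", sp, f"{label}_suitability.tif"),
                          smap.values.astype(np.float32), smap.grid)
            write_geotiff(_out(cfg, "project", sp, f"{label}_binary.tif"),
                          bmap.values, bmap.grid, nodata=None)
        logger.info("project %s: %d periods", sp, len(stacks))


def _read_binary(cfg: RunConfig, sp: str, label: str) -> ch.BinaryMap:
    path = Path(cfg.output_dir) / "project" / sp / f"{label}_binary.tif"
    if not path.exists():
        raise DependencyError(f"binary map missing: {path} (run 'project')")
    arr, grid, _ = read_geotiff(path)
    mask = np.ones(grid.shape, bool)
    return ch.BinaryMap(grid, arr.astype(np.uint8), mask)


def _read_suitability(cfg: RunConfig, sp: str, label: str) -> ch.SuitabilityMap:
    path = Path(cfg.output_dir) / "project" / sp / f"{label}_suitability.tif"
    if not path.exists():
        raise DependencyError(f"suitability map missing: {path} (run 'project')")
    arr, grid, nodata = read_geotiff(path)
    mask = np.isfinite(arr)
    if nodata is not None:
        mask &= arr != nodata
    return ch.SuitabilityMap(grid, np.where(mask, arr, np.nan), mask)


def _load_elevation(cfg: RunConfig) -> EnvStack | None:
    if not cfg.elevation:
        return None
    paths = ([Path(cfg.elevation)] if Path(cfg.elevation).is_file()
             else _tif_paths(cfg.elevation))
    stack = read_stack(paths[:1])
    if cfg.resample_cell_size:
        stack = resample_to(stack, cfg.resample_cell_size)
    return stack


def stage_change(cfg: RunConfig) -> None:
    species = [d.name for d in _species_dirs(cfg)]
    elevation = _load_elevation(cfg)
    periods = _periods(cfg)
    rows, crows = [], []
    for sp in species:
        base = _read_binary(cfg, sp, "baseline")
        for label in periods:
            bmap = base if label == "baseline" else _read_binary(cfg, sp, label)
            if label != "baseline":
                summary = ch.range_change(base, bmap)
                rows.append({"species": sp, "scenario": label, **summary.to_dict()})
            try:
                cen = ch.centroid(bmap, elevation)
                crows.append({"species": sp, "period": label,
                              "median_lon": cen.median_lon, "median_lat": cen.median_lat,
                              "median_elev": cen.median_elev, "n_cells": cen.n_cells})
            except Exception as exc:
                logger.warning("centroid %s/%s undefined: %s", sp, label, exc)
    pd.DataFrame(rows).to_csv(_out(cfg, "change", "change_summary.csv"), index=False)
    pd.DataFrame(crows).to_csv(_out(cfg, "change", "centroids.csv"), index=False)

    base_rich = None
    for label in periods:
        maps = [_read_binary(cfg, sp, label) for sp in species]
        rich = ch.richness(maps)
        write_geotiff(_out(cfg, "change", f"richness_{label}.tif"),
                      rich.sr.astype(np.int16), rich.grid, nodata=None)
        if label == "baseline":
            base_rich = rich
        else:
            delta = ch.richness_delta(rich, base_rich)
            write_geotiff(_out(cfg, "change", f"delta_sr_{label}.tif"),
                          delta.astype(np.int16), rich.grid, nodata=None)
    logger.info("change: %d species x %d scenarios summarized",
                len(species), len(periods) - 1)


def stage_overlap(cfg: RunConfig) -> None:
    species = [d.name for d in _species_dirs(cfg)]
    reader = _read_binary if cfg.d_mode == "binary" else _read_suitability
    matrices = {}
    for label in _periods(cfg):
        maps = {sp: reader(cfg, sp, label) for sp in species}
        m = ch.overlap_matrix(maps, mode=cfg.d_mode)
        matrices[label] = m
        m.to_frame().to_csv(_out(cfg, "overlap", f"d_{label}.csv"))
    rows = []
    base = matrices["baseline"]
    for label, m in matrices.items():
        if label == "baseline":
            continue
        for i, s1 in enumerate(m.species):
            for s2 in m.species[i + 1:]:
                d0, d1 = base.pair(s1, s2), m.pair(s1, s2)
                rel = (ch.relative_overlap_change(d0, d1) if d0 > 0 else np.nan)
                rows.append({"scenario": label, "species_1": s1, "species_2": s2,
                             "d_baseline": d0, "d_future": d1,
                             "relative_change_pct": rel})
    pd.DataFrame(rows).to_csv(_out(cfg, "overlap", "overlap_change.csv"), index=False)
    logger.info("overlap: %d matrices (%s mode)", len(matrices), cfg.d_mode)


def stage_report(cfg: RunConfig) -> None:
    out_root = Path(cfg.output_dir)
    if cfg.zones:
        zones = read_stack([Path(cfg.zones)])
        occ_by_species = OccurrenceSet.from_csv(cfg.occurrences_csv)
        tables = []
        for sp, occ in occ_by_species.items():
            t = ch.zone_frequency(occ, zones)
            t.insert(0, "species", sp)
            tables.append(t)
        pd.concat(tables, ignore_index=True).to_csv(
            _out(cfg, "report", "zone_frequency.csv"), index=False)
    artifacts = []
    for path in sorted(out_root.rglob("*")):
        if not path.is_file() or path.name == "manifest.json":
            continue
        rel = path.relative_to(out_root)
        artifacts.append({
            "path": str(rel),
            "stage": rel.parts[0] if len(rel.parts) > 1 else "run",
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        })
    manifest = {"master_seed": cfg.master_seed, "config": cfg.to_dict(),
                "artifacts": artifacts}
    with open(_out(cfg, "report", "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("report: manifest lists %d artifacts", len(artifacts))


_STAGE_FUNCS = {"screen": stage_screen, "fit": stage_fit, "project": stage_project,
                "change": stage_change, "overlap": stage_overlap,
                "report": stage_report}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> int:
    """Run the requested stages in canonical order; returns 0 on success.

    A stage failure is logged with the stage name and stops the run with a
    nonzero status; artifacts written so far are retained alongside a
    ``FAILED_<stage>`` marker file.
    """
    stages = list(stages) if stages else list(STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    Path(cfg.output_dir).mkdir(parents=True, exist_ok=True)
    cfg.echo(_out(cfg, "resolved_config.yaml"))
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            _out(cfg, f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
            return 1
    return 0
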