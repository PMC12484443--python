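"""End-to-end pipeline: synthetic (or user) inputs -> travel-time surfaces
-> coverage and equity tables, with a QC report.

The full design accumulates one travel-time surface per (facility stratum x
speed scenario) pair — 12 surfaces for four strata and three scenarios —
then summarises them into zonal statistics, threshold coverage, wealth-
quintile equiplot rows and urbanicity-band means.  Everything is
deterministic given the configuration and its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as aio
from .classes import SCENARIOS, STRATA
from .coverage import DEFAULT_THRESHOLDS, coverage, mask_populated, zonal_stats
from .equity import assign_quintiles, equiplot_table, match_rwi, urbanicity_summary
from .grid import GridSpec
from .landscape import (
    LandscapeConfig,
    gen_facilities,
    gen_landscape,
    gen_population_rwi_urbanicity,
    gen_trajectories,
)
from .speeds import (
    aggregate_speed_table,
    default_speed_table,
    match_to_road,
    point_pair_speeds,
)
from .traveltime import run_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``synthetic`` blocks (requiring a seed) or file paths under
    ``inputs`` supply each layer; analysis settings pick the strata,
    scenarios, thresholds and grid connectivity.
    """

    output_dir: str = "accessim_out"
    seed: Optional[int] = None
    grid: Dict = field(default_factory=lambda: {"n_rows": 100, "n_cols": 100,
                                                "cell_size": 30.0})
    synthetic: Optional[Dict] = field(default_factory=dict)
    inputs: Dict = field(default_factory=dict)
    strata: Sequence[str] = STRATA
    scenarios: Sequence[str] = SCENARIOS
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    connectivity: int = 8
    match_buffer: float = 20.0
    min_pop: float = 0.0

    @classmethod
    def from_dict(cls, doc: Dict) -> "PipelineConfig":
        validate_config(doc)
        known = {f.name for f in dc_fields(cls)}
        return cls(**{k: v for k, v in doc.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(doc: Dict) -> None:
    """Schema check before any computation; raises ValueError on problems."""
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    synthetic = doc.get("synthetic")
    uses_synthetic = synthetic is not None and doc.get("inputs") in (None, {})
    if uses_synthetic and doc.get("seed") is None:
        raise ValueError("a seed is mandatory when synthetic inputs are used")
    for key, allowed in (("strata", STRATA), ("scenarios", SCENARIOS)):
        vals = doc.get(key)
        if vals is not None:
            bad = set(vals) - set(allowed)
            if bad:
                raise ValueError(f"unknown {key} {sorted(bad)}")
    thr = doc.get("thresholds")
    if thr is not None and (any(t <= 0 for t in thr) or sorted(thr) != list(thr)):
        raise ValueError("thresholds must be positive and ascending")
    if doc.get("connectivity", 8) not in (8, 16):
        raise ValueError("connectivity must be 8 or 16")


def _build_inputs(cfg: PipelineConfig):
    """Generate synthetic layers or read user-supplied files."""
    if cfg.inputs:
        dem = aio.read_raster(cfg.inputs["dem"]) if "dem" in cfg.inputs else None
        landcover = aio.read_raster(cfg.inputs["landcover"], dtype=np.int16)
        roads = aio.read_roads(cfg.inputs["roads"])
        registry = aio.read_facilities(cfg.inputs["facilities"])
        pop = aio.read_raster(cfg.inputs["population"])
        rwi = aio.read_rwi(cfg.inputs["rwi"]) if "rwi" in cfg.inputs else None
        urb = (aio.read_raster(cfg.inputs["urbanicity"], dtype=np.int16)
               if "urbanicity" in cfg.inputs else None)
        zones = aio.read_zones(cfg.inputs["zones"]) if "zones" in cfg.inputs else None
        trajectories = (aio.read_trajectories(cfg.inputs["trajectories"])
                        if "trajectories" in cfg.inputs else None)
        return dem, landcover, roads, registry, pop, rwi, urb, zones, trajectories

    spec = GridSpec(**cfg.grid)
    syn = cfg.synthetic or {}
    lcfg = LandscapeConfig(**syn.get("landscape", {}))
    dem, landcover, roads, zones = gen_landscape(spec, lcfg, seed=cfg.seed)
    pop, rwi, urb = gen_population_rwi_urbanicity(spec, lcfg, seed=cfg.seed + 1)
    fac_kwargs = dict(syn.get("facilities", {}))
    counts = fac_kwargs.pop("counts", None)
    if counts is not None:
        counts = {k: tuple(v) for k, v in counts.items()}
    registry = gen_facilities(
        spec, counts=counts, seed=cfg.seed + 2, pop=pop, roads=roads, **fac_kwargs
    )
    traj_kwargs = dict(syn.get("trajectories", {}))
    n_trips = traj_kwargs.pop("n_trips", 3 * len(roads))
    trajectories = gen_trajectories(
        roads, default_speed_table(), n_trips=n_trips, seed=cfg.seed + 3,
        **traj_kwargs,
    )
    return dem, landcover, roads, registry, pop, rwi, urb, zones, trajectories


def run_pipeline(config: PipelineConfig | Dict) -> Path:
    """Run the full design; returns the output directory.

    Writes per-(stratum, scenario) travel-time rasters, the estimated speed
    table, zonal/coverage/equiplot/urbanicity CSVs and a QC report.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc: Dict = {"stages": {}}

    dem, landcover, roads, registry, pop, rwi, urb, zones, trajectories = (
        _build_inputs(config)
    )

    # --- speed survey -----------------------------------------------------
    if trajectories:
        obs = []
        for traj in trajectories:
            matches = match_to_road(traj, roads, buffer=config.match_buffer)
            obs.extend(point_pair_speeds(traj, matches))
        sqc: Dict = {}
        present = sorted(
            roads.classes_present() - {"others"}
        )
        table = aggregate_speed_table(
            obs, required_classes=present + ["others"], qc=sqc
        )
        qc["stages"]["speed_survey"] = dict(
            n_observations=len(obs), **sqc
        )
    else:
        table = default_speed_table()
        qc["stages"]["speed_survey"] = {"note": "no trajectories; default table used"}
    table.to_csv(out / "speed_table.csv")

    # --- travel time ------------------------------------------------------
    surfaces = run_matrix(
        roads, landcover, dem, table, registry,
        strata=config.strata, scenarios=config.scenarios,
        connectivity=config.connectivity,
    )
    unreachable: Dict[str, int] = {}
    zonal_frames: List[pd.DataFrame] = []
    cov_frames: List[pd.DataFrame] = []
    equi_frames: List[pd.DataFrame] = []
    urb_frames: List[pd.DataFrame] = []

    rwi_cells = match_rwi(next(iter(surfaces.values())), rwi) if rwi else None
    assignment = (
        assign_quintiles(rwi_cells.data, np.asarray(pop.data, float))
        if rwi_cells is not None else None
    )

    for (stratum, scenario), tt in surfaces.items():
        aio.write_raster(tt, out / f"tt_{stratum}_{scenario}.asc")
        masked = mask_populated(tt, pop, min_pop=config.min_pop)
        pop_mask = np.asarray(pop.data, float) > config.min_pop
        unreachable[f"{stratum}/{scenario}"] = int(
            (~np.isfinite(np.asarray(masked.data, float)) & pop_mask).sum()
        )
        if zones is not None:
            zonal_frames.append(zonal_stats(masked, zones, pop))
            cov_frames.append(
                coverage(masked, pop, zones, thresholds=config.thresholds)
            )
        if assignment is not None:
            equi_frames.append(equiplot_table(masked, assignment, zones))
        if urb is not None:
            urb_frames.append(urbanicity_summary(masked, urb, pop))

    qc["stages"]["travel_time"] = {"unreachable_populated_cells": unreachable}

    if zonal_frames:
        pd.concat(zonal_frames, ignore_index=True).to_csv(
            out / "zonal_stats.csv", index=False
        )
        cov = pd.concat(cov_frames, ignore_index=True)
        cov.to_csv(out / "coverage.csv", index=False)
        wide = (
            cov.pivot_table(
                index=["zone_id", "zone_level", "stratum", "threshold"],
                columns="scenario", values="pct_wocba",
            )
            .round(1)
            .reset_index()
        )
        wide.to_csv(out / "coverage_by_scenario.csv", index=False)
    if equi_frames:
        pd.concat(equi_frames, ignore_index=True).to_csv(
            out / "equiplot.csv", index=False
        )
    if urb_frames:
        pd.concat(urb_frames, ignore_index=True).to_csv(
            out / "urbanicity.csv", index=False
        )

    qc["facilities"] = {
        "total": len(registry),
        "public": registry.n_public(),
        "private": registry.n_private(),
    }
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc, fh, indent=1, sort_keys=True)
    return out
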