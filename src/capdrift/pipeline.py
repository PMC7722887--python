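"""Experiment orchestration: scenario grids, run manifests, reproducible CSVs.

A run manifest (YAML/dict) names one experiment — ``vertical_movement``,
``source_populations``, ``functional_connectivity`` or ``hydrography`` —
together with the ocean source (synthetic cap parameters or NetCDF paths),
the scenario grid (release depths x durations x seasons x directions) and a
seed.  ``run_experiment`` executes seeding -> tracking -> statistics for
every scenario cell, writes the statistics as CSV into an output directory
and copies the fully-resolved manifest next to them; re-running the same
manifest reproduces byte-identical outputs.

A scenario whose release depth exceeds every polygon's seafloor yields an
empty seeding; the run logs a warning for that cell and continues.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import hydrography as hydro
from .grid_flow import read_field_netcdf
from .seeding import (
    DURATION_PRESETS_DAYS,
    EmptySeedWarning,
    RELEASE_DEPTH_PRESETS,
    seed_area_set,
    seed_domain,
)
from .synthetic_ocean import (
    SEASON_MONTHS,
    CapParams,
    ClosedAreaSet,
    default_grid,
    make_cap_circulation,
    make_closed_areas,
    make_seamount_bathymetry,
    make_ts_climatology,
)
from .tracker import TrackerConfig, advect

__all__ = ["run_experiment", "build_ocean", "season_field", "DEFAULT_MANIFEST"]

log = logging.getLogger("capdrift")

CSV_FLOAT_FORMAT = "%.6g"

DEFAULT_MANIFEST = {
    "experiment": "vertical_movement",
    "seed": 0,
    "ocean": {"synthetic": {}},          # CapParams overrides, or netcdf paths
    "grid_spacing": 0.1,                  # synthetic ocean grid spacing (deg)
    "seed_spacing": 0.02,                 # particle lattice spacing (deg)
    "depths": None,                       # None -> experiment preset
    "durations_days": list(DURATION_PRESETS_DAYS),
    "seasons": ["average"],               # average | winter|spring|summer|autumn
    "directions": ["forward"],
    "group": "sponges",                   # functional_connectivity only
    "K_h": 100.0,
    "dt": 1200.0,
    "record_every": 1,
    "ttd_bin_days": 1.0,
    "source_bin_deg": 0.1,
    "hydro_years": 5,
    "hydro_noise_std_t": 0.05,
    "hydro_noise_std_s": 0.005,
    "store_trajectories": False,
}


def _resolve_manifest(config: dict) -> dict:
    man = copy.deepcopy(DEFAULT_MANIFEST)
    man.update(copy.deepcopy(config))
    if man["depths"] is None:
        exp = man["experiment"]
        key = man["group"] if exp == "functional_connectivity" else exp
        man["depths"] = list(RELEASE_DEPTH_PRESETS.get(key, (1000.0,)))
    return man


def build_ocean(man: dict):
    """(bathy, flow, areas, params) from the manifest's ocean section."""
    ocean = man.get("ocean", {})
    if "synthetic" in ocean:
        overrides = ocean["synthetic"] or {}
        valid = {f.name for f in dc_fields(CapParams)}
        params = CapParams(**{k: v for k, v in overrides.items() if k in valid})
        grid = default_grid(params, spacing=man["grid_spacing"])
        bathy = make_seamount_bathymetry(params, grid)
        flow = make_cap_circulation(bathy, params, depths=grid.depths)
        areas = make_closed_areas(params, bathy)
        return bathy, flow, areas, params
    bathy = read_field_netcdf(ocean["bathymetry"], "bathymetry")
    flow = read_field_netcdf(ocean["flow"], "flow")
    areas = ClosedAreaSet.from_geojson(ocean["areas"])
    return bathy, flow, areas, None


def season_field(flow, season: str):
    """Steady field for a named season, the annual mean, or the full cycle."""
    if season == "average":
        return flow.time_mean()
    if season == "monthly":
        return flow
    return flow.time_mean(SEASON_MONTHS[season])


def _tracker_config(man, duration, direction):
    return TrackerConfig(dt=man["dt"], K_h=man["K_h"], direction=direction,
                         duration_days=duration, rng_seed=int(man["seed"]),
                         record_every=int(man["record_every"]))


def run_experiment(config: dict, out_dir) -> dict:
    """Execute one experiment manifest; returns {name: artifact path}."""
    man = _resolve_manifest(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp = man["experiment"]
    runner = {
        "vertical_movement": _run_vertical_movement,
        "source_populations": _run_source_populations,
        "functional_connectivity": _run_functional_connectivity,
        "hydrography": _run_hydrography,
    }.get(exp)
    if runner is None:
        raise ValueError(f"unknown experiment {exp!r}")
    artifacts = runner(man, out)
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(man, fh, sort_keys=True)
    artifacts["manifest"] = manifest_path
    return artifacts


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT,
              lineterminator="\n")
    return path


def _seed_scenario(man, areas, bathy, depth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptySeedWarning)
        return seed_area_set(areas, man["seed_spacing"], depth, bathy)


def _run_vertical_movement(man, out: Path) -> dict:
    bathy, flow, areas, _ = build_ocean(man)
    rows = []
    for season in man["seasons"]:
        fld = season_field(flow, season)
        for depth in man["depths"]:
            seeds = _seed_scenario(man, areas, bathy, depth)
            if not seeds:
                log.warning("no seeds at %s m; scenario skipped", depth)
                continue
            for duration in man["durations_days"]:
                cfg = _tracker_config(man, duration, "forward")
                traj = advect(seeds, fld, cfg, bathy)
                vs = conn.vertical_stats(traj, release_depth=depth)
                rows.append(dict(
                    season=season, release_depth_m=depth,
                    duration_days=duration, n_particles=vs.n_particles,
                    min_depth_reached_m=vs.min_reached,
                    min_depth_p25_m=vs.min_p[25], min_depth_p50_m=vs.min_p[50],
                    min_depth_p75_m=vs.min_p[75],
                    max_depth_p25_m=vs.max_p[25], max_depth_p50_m=vs.max_p[50],
                    max_depth_p75_m=vs.max_p[75],
                    max_depth_reached_m=vs.max_reached))
                log.info("vertical_movement %s depth=%s dur=%s done",
                         season, depth, duration)
    path = _write_csv(pd.DataFrame(rows), out / "vertical_stats.csv")
    return {"vertical_stats": path}


def _run_source_populations(man, out: Path) -> dict:
    bathy, flow, areas, _ = build_ocean(man)
    fld = season_field(flow, man["seasons"][0])
    depth = man["depths"][0]
    artifacts = {}
    prop_rows = []
    for direction in man["directions"]:
        for duration in man["durations_days"]:
            cfg = _tracker_config(man, duration, direction)
            if direction == "forward":
                seeds = seed_domain(man["seed_spacing"], depth, bathy,
                                    cfg.domain_box)
                positions = "initial"
            else:
                seeds = _seed_scenario(man, areas, bathy, depth)
                positions = "final"
            traj = advect(seeds, fld, cfg, bathy)
            visits = conn.detect_visits(traj, areas)
            sdm = conn.source_density_map(traj, visits,
                                          bin_deg=man["source_bin_deg"],
                                          positions=positions)
            name = f"source_density_{direction}_{int(duration)}d"
            artifacts[name] = _write_csv(sdm.cells, out / f"{name}.csv")
            for j, aid in enumerate(visits.area_ids):
                got = visits.visited(aid) | (visits.terminal == aid)
                prop_rows.append(dict(
                    direction=direction, duration_days=duration, area_id=aid,
                    n_released=traj.n_particles, n_arrived=int(np.sum(got)),
                    proportion=float(np.mean(got))))
    artifacts["area_proportions"] = _write_csv(
        pd.DataFrame(prop_rows), out / "area_proportions.csv")
    return artifacts


def _run_functional_connectivity(man, out: Path) -> dict:
    bathy, flow, areas, _ = build_ocean(man)
    group_areas = areas.group(man["group"])
    artifacts = {}
    matrices = {}
    ttd_frames = []
    for season in man["seasons"]:
        fld = season_field(flow, season)
        for depth in man["depths"]:
            seeds = _seed_scenario(man, group_areas, bathy, depth)
            if not seeds:
                log.warning("group %s: no seeds at %s m; scenario skipped",
                            man["group"], depth)
                continue
            for duration in man["durations_days"]:
                for direction in man["directions"]:
                    cfg = _tracker_config(man, duration, direction)
                    traj = advect(seeds, fld, cfg, bathy)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        visits = conn.detect_visits(traj, group_areas)
                        mat = conn.connectivity_matrix(
                            visits, metadata=dict(
                                season=season, depth=depth,
                                duration_days=duration, direction=direction))
                    key = (season, depth, duration, direction)
                    matrices[key] = mat
                    tag = f"{season}_{int(depth)}m_{int(duration)}d_{direction}"
                    df = mat.to_dataframe()
                    df.insert(0, "source_area", mat.area_ids)
                    artifacts[f"matrix_{tag}"] = _write_csv(
                        df, out / f"connectivity_{tag}.csv")
                    ttd = conn.transit_time_distribution(
                        visits, man["ttd_bin_days"]).to_dataframe()
                    ttd.insert(0, "scenario", tag)
                    ttd_frames.append(ttd)
                    log.info("functional_connectivity %s done", tag)
    if ttd_frames:
        artifacts["ttd"] = _write_csv(
            pd.concat(ttd_frames, ignore_index=True), out / "ttd.csv")
    # seasonal cross-correlations against the averaged model, per depth
    corr_rows = []
    seasons = [s for s in man["seasons"] if s != "average"]
    if "average" in man["seasons"] and seasons:
        for depth in man["depths"]:
            for duration in man["durations_days"]:
                for direction in man["directions"]:
                    base = matrices.get(("average", depth, duration, direction))
                    for season in seasons:
                        m = matrices.get((season, depth, duration, direction))
                        if base is None or m is None:
                            continue
                        try:
                            r = conn.matrix_correlation(base, m)
                        except ValueError:
                            r = np.nan
                        corr_rows.append(dict(
                            depth_m=depth, duration_days=duration,
                            direction=direction, season=season, pearson_r=r))
    if corr_rows:
        artifacts["seasonal_correlation"] = _write_csv(
            pd.DataFrame(corr_rows), out / "seasonal_correlation.csv")
    return artifacts


def _run_hydrography(man, out: Path) -> dict:
    bathy, flow, areas, params = build_ocean(man)
    if params is None:
        raise ValueError("hydrography experiment requires a synthetic ocean")
    temp, salt = make_ts_climatology(
        bathy, params, years=int(man["hydro_years"]),
        noise_std_t=man["hydro_noise_std_t"],
        noise_std_s=man["hydro_noise_std_s"], seed=int(man["seed"]))
    table = hydro.area_bottom_series(temp, salt, areas)
    artifacts = {"bottom_series": _write_csv(table, out / "bottom_series.csv")}

    # along-pathway stability from backward runs out of each closed area
    fld = season_field(flow, man["seasons"][0])
    depth = man["depths"][0] if man["depths"] else 1000.0
    seeds = _seed_scenario(man, areas, bathy, depth)
    if seeds:
        cfg = _tracker_config(man, man["durations_days"][0], "backward")
        traj = advect(seeds, fld, cfg, bathy)
        temp_c, salt_c = make_ts_climatology(bathy, params)
        artifacts["track_ts"] = _write_csv(
            hydro.track_ts(traj, temp_c, salt_c), out / "track_ts.csv")
    return artifacts
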