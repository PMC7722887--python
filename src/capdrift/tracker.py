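"""Lagrangian engine: RK4 advection with horizontal random-walk diffusion.

Particles follow the classical kinematics x_t = x_0 + integral of v dt,
integrated with a fourth-order Runge-Kutta scheme (default time step 20 min)
on the interpolated velocity field, plus an uncorrelated Gaussian random walk
per horizontal axis with standard deviation sqrt(2 * K_h * dt) meters
(default K_h = 100 m^2/s); there is no vertical diffusion.  Backward runs
negate the velocity and march the climatological time argument backward; the
random walk is kept as a forward walk (it is sign-symmetric), a standard
heuristic rather than an exact adjoint.

Particles are removed when their horizontal position leaves the configured
domain box (or the gridded field's own bounding box, whichever is hit
first); depth is clamped to [0, local seafloor] and a particle only grounds
when its horizontal cell is land.  Per-run randomness comes from a single
seeded Generator, with one draw pair per particle per step in a fixed order,
so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
import xarray as xr

from .grid_flow import (
    NETCDF_ENGINE,
    SAMPLE_GROUNDED,
    SAMPLE_OK,
    SAMPLE_OUT_OF_DOMAIN,
    Bathymetry,
    FlowField,
    sample_velocity_arrays,
)

__all__ = [
    "TrackerConfig",
    "ParticleState",
    "TrajectorySet",
    "STATUS_ACTIVE",
    "STATUS_REMOVED_BOUNDARY",
    "STATUS_GROUNDED",
    "SECONDS_PER_MONTH",
    "rk4_displacement",
    "diffusion_displacement",
    "step",
    "advect",
]

STATUS_ACTIVE = 0
STATUS_REMOVED_BOUNDARY = 1
STATUS_GROUNDED = 2

SECONDS_PER_MONTH = 365.25 * 86400.0 / 12.0  # climatological month

# Model-domain box of the study region (lon_min, lon_max, lat_min, lat_max):
# 73.9-31.4 W, 40.8-70.5 N.
DEFAULT_DOMAIN_BOX = (-73.9, -31.4, 40.8, 70.5)


@dataclass(frozen=True)
class TrackerConfig:
    """Integration parameters; defaults follow the study configuration."""

    dt: float = 1200.0                    # s (20 min)
    K_h: float = 100.0                    # m^2/s horizontal mixing
    direction: str = "forward"            # or "backward"
    duration_days: float = 30.0           # presets: 14, 30, 90
    rng_seed: int = 0
    record_every: int = 1                 # record every k-th step
    domain_box: tuple = DEFAULT_DOMAIN_BOX
    earth_radius: float = 6_371_000.0     # m

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.K_h < 0:
            raise ValueError("K_h must be >= 0")
        if self.duration_days <= 0:
            raise ValueError("duration must be > 0")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 86400.0 / self.dt))

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "forward" else -1.0


@dataclass
class ParticleState:
    """Position (degrees, m down) and life-cycle status of one particle."""

    lon: float
    lat: float
    depth: float
    status: int = STATUS_ACTIVE
    release_lon: float = math.nan
    release_lat: float = math.nan
    release_depth: float = math.nan
    release_time: float = 0.0   # fractional month of release
    area_id: int = -1           # source closed area, -1 if none

    def __post_init__(self):
        if math.isnan(self.release_lon):
            self.release_lon = self.lon
            self.release_lat = self.lat
            self.release_depth = self.depth


@dataclass
class TrajectorySet:
    """Recorded positions/status of an ensemble, plus per-particle extremes.

    ``lon``/``lat``/``depth``/``status`` have shape (n_particles, n_records);
    removed particles hold NaN positions after removal, grounded particles
    hold their frozen position.  ``times`` is elapsed seconds since release
    at each record (uniform at dt * record_every).
    """

    times: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    status: np.ndarray
    release_lon: np.ndarray
    release_lat: np.ndarray
    release_depth: np.ndarray
    release_time: float
    source_area: np.ndarray
    min_depth: np.ndarray
    max_depth: np.ndarray
    config: TrackerConfig

    @property
    def n_particles(self) -> int:
        return self.lon.shape[0]

    @property
    def n_records(self) -> int:
        return self.lon.shape[1]

    def final_positions(self):
        """Last recorded in-domain (lon, lat, depth) per particle."""
        valid = np.isfinite(self.lon)
        # index of last valid record per particle
        idx = valid.shape[1] - 1 - np.argmax(valid[:, ::-1], axis=1)
        rows = np.arange(self.n_particles)
        return (self.lon[rows, idx], self.lat[rows, idx],
                self.depth[rows, idx])

    def status_counts(self, record: int = -1) -> dict[int, int]:
        vals, counts = np.unique(self.status[:, record], return_counts=True)
        return {int(s): int(c) for s, c in zip(vals, counts)}

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {
                "lon": (("particle", "obs"), self.lon),
                "lat": (("particle", "obs"), self.lat),
                "depth": (("particle", "obs"), self.depth),
                "status": (("particle", "obs"), self.status.astype("i4")),
                "release_lon": (("particle",), self.release_lon),
                "release_lat": (("particle",), self.release_lat),
                "release_depth": (("particle",), self.release_depth),
                "source_area": (("particle",), self.source_area.astype("i4")),
                "min_depth": (("particle",), self.min_depth),
                "max_depth": (("particle",), self.max_depth),
            },
            coords={"time": (("obs",), self.times, {"units": "s"})},
            attrs={
                "dt": self.config.dt,
                "K_h": self.config.K_h,
                "direction": self.config.direction,
                "duration_days": self.config.duration_days,
                "rng_seed": self.config.rng_seed,
                "record_every": self.config.record_every,
                "domain_box": list(self.config.domain_box),
                "release_time": self.release_time,
            },
        )
        ds.to_netcdf(path, engine=NETCDF_ENGINE)

    @classmethod
    def from_netcdf(cls, path) -> "TrajectorySet":
        with xr.open_dataset(path, engine=NETCDF_ENGINE,
                             decode_times=False) as ds:
            ds = ds.load()
        cfg = TrackerConfig(
            dt=float(ds.attrs["dt"]), K_h=float(ds.attrs["K_h"]),
            direction=str(ds.attrs["direction"]),
            duration_days=float(ds.attrs["duration_days"]),
            rng_seed=int(ds.attrs["rng_seed"]),
            record_every=int(ds.attrs["record_every"]),
            domain_box=tuple(np.asarray(ds.attrs["domain_box"], float)))
        return cls(
            times=ds["time"].values, lon=ds["lon"].values,
            lat=ds["lat"].values, depth=ds["depth"].values,
            status=ds["status"].values.astype(np.int8),
            release_lon=ds["release_lon"].values,
            release_lat=ds["release_lat"].values,
            release_depth=ds["release_depth"].values,
            release_time=float(ds.attrs.get("release_time", 0.0)),
            source_area=ds["source_area"].values.astype(int),
            min_depth=ds["min_depth"].values,
            max_depth=ds["max_depth"].values, config=cfg)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _deg_per_meter(lat, earth_radius):
    """(deg lon per m east, deg lat per m north) at given latitude."""
    k = 180.0 / (math.pi * earth_radius)
    return k / np.cos(np.radians(lat)), k


def _stage_sample(field, lon, lat, depth, tmonth, sign):
    u, v, w, st = sample_velocity_arrays(field, lon, lat, depth, tmonth)
    return sign * u, sign * v, sign * w, st


def rk4_displacement(field: FlowField, lon, lat, depth, t_month,
                     dt: float, direction: str = "forward",
                     earth_radius: float = 6_371_000.0):
    """One RK4 step over the interpolated velocity, vectorized over particles.

    Returns (dlon, dlat, ddepth, status): degrees, degrees, meters (positive
    down, so ddepth = -w dt for positive-up w).  A stage falling outside the
    grid box marks the particle ``removed_boundary``; an all-masked stage
    marks it ``grounded``; flagged particles get zero displacement.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    depth = np.atleast_1d(np.asarray(depth, dtype=float))
    sign = 1.0 if direction == "forward" else -1.0
    dtm = sign * dt / SECONDS_PER_MONTH

    status = np.full(lon.shape, SAMPLE_OK, dtype=np.int8)

    def stage(dl, da, dd, frac):
        u, v, w, st = _stage_sample(field, lon + dl, lat + da, depth + dd,
                                    t_month + frac * dtm, sign)
        np.copyto(status, st, where=(status == SAMPLE_OK) & (st != SAMPLE_OK))
        u = np.nan_to_num(u)
        v = np.nan_to_num(v)
        w = np.nan_to_num(w)
        dpl, dpa = _deg_per_meter(np.clip(lat + da, -89.9, 89.9), earth_radius)
        return u * dpl, v * dpa, -w  # deg/s, deg/s, m/s (down-positive)

    k1 = stage(0.0, 0.0, 0.0, 0.0)
    k2 = stage(0.5 * dt * k1[0], 0.5 * dt * k1[1], 0.5 * dt * k1[2], 0.5)
    k3 = stage(0.5 * dt * k2[0], 0.5 * dt * k2[1], 0.5 * dt * k2[2], 0.5)
    k4 = stage(dt * k3[0], dt * k3[1], dt * k3[2], 1.0)

    out = []
    for i in range(3):
        d = dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        out.append(np.where(status == SAMPLE_OK, d, 0.0))
    return out[0], out[1], out[2], status


def diffusion_displacement(rng: np.random.Generator, K_h: float, dt: float,
                           lat, earth_radius: float = 6_371_000.0):
    """Random-walk step: independent N(0, sqrt(2 K_h dt)) meters per axis,
    converted to degrees at the particle latitude.  No vertical component."""
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if K_h == 0.0:
        z = np.zeros(lat.shape)
        return z, z.copy()
    sigma = math.sqrt(2.0 * K_h * dt)
    draws = rng.standard_normal(size=lat.shape + (2,)) * sigma
    dpl, dpa = _deg_per_meter(lat, earth_radius)
    return draws[..., 0] * dpl, draws[..., 1] * dpa


def _in_box(lon, lat, box):
    return ((lon >= box[0]) & (lon <= box[1])
            & (lat >= box[2]) & (lat <= box[3]))


def step(state: ParticleState, field: FlowField, t_month: float,
         config: TrackerConfig, bathy: Bathymetry | None = None,
         rng: np.random.Generator | None = None) -> ParticleState:
    """Advance a single particle one time step (convenience wrapper)."""
    if state.status != STATUS_ACTIVE:
        return state
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    lon = np.array([state.lon])
    lat = np.array([state.lat])
    depth = np.array([state.depth])
    new_lon, new_lat, new_depth, status = _advance(
        lon, lat, depth, np.array([STATUS_ACTIVE], dtype=np.int8),
        field, t_month, config, bathy, rng)
    return replace(state, lon=float(new_lon[0]), lat=float(new_lat[0]),
                   depth=float(new_depth[0]), status=int(status[0]))


def _advance(lon, lat, depth, status, field, t_month, config, bathy, rng):
    """One integration step for an ensemble; returns updated copies."""
    active = status == STATUS_ACTIVE
    dlon, dlat, ddepth, st = rk4_displacement(
        field, lon, lat, depth, t_month, config.dt, config.direction,
        config.earth_radius)
    if config.K_h > 0.0:
        # one draw pair per particle per step, fixed order (reproducibility)
        ddlon, ddlat = diffusion_displacement(
            rng, config.K_h, config.dt, lat, config.earth_radius)
    else:
        ddlon = ddlat = 0.0

    new_status = status.copy()
    stage_removed = active & (st == SAMPLE_OUT_OF_DOMAIN)
    stage_grounded = active & (st == SAMPLE_GROUNDED)
    new_status[stage_removed] = STATUS_REMOVED_BOUNDARY
    new_status[stage_grounded] = STATUS_GROUNDED
    moving = new_status == STATUS_ACTIVE

    cand_lon = np.where(moving, lon + dlon + ddlon, lon)
    cand_lat = np.where(moving, lat + dlat + ddlat, lat)
    cand_depth = np.where(moving, depth + ddepth, depth)

    glon0, glon1, glat0, glat1 = field.grid.horizontal_box()
    inside = _in_box(cand_lon, cand_lat, config.domain_box) & \
        _in_box(cand_lon, cand_lat, (glon0, glon1, glat0, glat1))
    exited = moving & ~inside
    new_status[exited] = STATUS_REMOVED_BOUNDARY
    moving = new_status == STATUS_ACTIVE

    new_lon = np.where(moving, cand_lon, lon)
    new_lat = np.where(moving, cand_lat, lat)
    new_depth = np.where(moving, cand_depth, depth)

    # vertical clamping to [0, seafloor]; grounding only over land columns
    new_depth = np.maximum(new_depth, 0.0)
    if bathy is not None:
        sf = bathy.depth_at(new_lon, new_lat)
        landed = moving & ~np.isfinite(sf)
        new_status[landed] = STATUS_GROUNDED
        ok = moving & np.isfinite(sf)
        new_depth = np.where(ok, np.minimum(new_depth, sf), new_depth)
    else:
        new_depth = np.minimum(new_depth, field.grid.depths[-1])
    return new_lon, new_lat, new_depth, new_status


def advect(seeds: Sequence[ParticleState], field: FlowField,
           config: TrackerConfig, bathy: Bathymetry | None = None,
           release_time: float = 0.0) -> TrajectorySet:
    """Integrate an ensemble for the configured duration.

    Particle count is conserved across status classes at every record
    (active + removed_boundary + grounded == seeded).  Backward runs march
    the climatological time argument backward with negated velocities.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed list")
    n = len(seeds)
    lon = np.array([s.lon for s in seeds], dtype=float)
    lat = np.array([s.lat for s in seeds], dtype=float)
    depth = np.array([s.depth for s in seeds], dtype=float)
    status = np.array([s.status for s in seeds], dtype=np.int8)
    source_area = np.array([s.area_id for s in seeds], dtype=int)

    n_steps = config.n_steps
    rec_idx = np.arange(0, n_steps + 1, config.record_every)
    n_rec = len(rec_idx)
    rec_set = set(rec_idx.tolist())

    R = dict(
        times=rec_idx * config.dt,
        lon=np.full((n, n_rec), np.nan), lat=np.full((n, n_rec), np.nan),
        depth=np.full((n, n_rec), np.nan),
        status=np.zeros((n, n_rec), dtype=np.int8),
    )
    min_d = depth.copy()
    max_d = depth.copy()
    rng = np.random.default_rng(config.rng_seed)

    def record(r):
        present = status != STATUS_REMOVED_BOUNDARY
        R["lon"][present, r] = lon[present]
        R["lat"][present, r] = lat[present]
        R["depth"][present, r] = depth[present]
        R["status"][:, r] = status

    r = 0
    record(r)
    dtm = config.sign * config.dt / SECONDS_PER_MONTH
    for istep in range(1, n_steps + 1):
        t_month = release_time + (istep - 1) * dtm
        lon, lat, depth, status = _advance(
            lon, lat, depth, status, field, t_month, config, bathy, rng)
        active = status == STATUS_ACTIVE
        min_d = np.where(active, np.minimum(min_d, depth), min_d)
        max_d = np.where(active, np.maximum(max_d, depth), max_d)
        if istep in rec_set:
            r += 1
            record(r)

    return TrajectorySet(
        times=R["times"], lon=R["lon"], lat=R["lat"], depth=R["depth"],
        status=R["status"],
        release_lon=np.array([s.release_lon for s in seeds]),
        release_lat=np.array([s.release_lat for s in seeds]),
        release_depth=np.array([s.release_depth for s in seeds]),
        release_time=release_time, source_area=source_area,
        min_depth=min_d, max_depth=max_d, config=config)
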