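"""Synthetic seamount-cap ocean: bathymetry, circulation, hydrography, closures.

The generator emulates the circulation structure around an isolated
bathymetric "cap" rising from an abyssal plain, of the kind that steers a
slope-following boundary current:

* a Gaussian seamount, ``H(r) = abyss - (abyss - summit) * exp(-r^2/R^2)``;
* an anticyclonic (clockwise, viewed from above) jet built from a
  streamfunction of seafloor depth, so horizontal flow is non-divergent and
  tangent to isobaths, peaking over a chosen core isobath — the kinematic
  analogue of a deep slope current;
* prescribed vertical velocity: downward over the upper slope, upward over
  the deep slope/offshore, zero in the surface layer, with a seasonal
  amplitude cycle peaking in late summer;
* a stable, cold (< 4 degC) and salty (> 34.8) bottom hydrography with an
  optional small interannual noise for multi-year series;
* a ring of 14 closed-area polygons (annular sectors) whose seafloor depth
  ranges bracket the release-depth presets of the tracking experiments, with
  two deliberately shallow areas (7 and 14) whose maximum depth is ~700 m.

Everything is kinematic: w is prescribed independently of horizontal
continuity, which is acceptable for a test ocean whose job is to exercise
the tracker and the statistics, not to satisfy primitive equations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.special import erf
from shapely.geometry import Polygon, mapping, shape

from .grid_flow import (
    Bathymetry,
    FieldValidationError,
    FlowField,
    Grid3D,
    ScalarField,
)

__all__ = [
    "CapParams",
    "ClosedArea",
    "ClosedAreaSet",
    "default_grid",
    "make_seamount_bathymetry",
    "make_cap_circulation",
    "make_analytic_flow",
    "make_ts_climatology",
    "make_closed_areas",
    "SEASON_MONTHS",
    "KM_PER_DEG_LAT",
]

KM_PER_DEG_LAT = 6371.0 * math.pi / 180.0  # 111.195 km

# Northern-hemisphere season -> calendar months (DJF convention).
SEASON_MONTHS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}

DEFAULT_DEPTHS = np.array(
    [0.0, 25.0, 50.0, 100.0, 200.0, 350.0, 550.0, 800.0, 1100.0, 1450.0,
     1850.0, 2300.0, 2800.0, 3400.0, 4000.0]
)


@dataclass(frozen=True)
class CapParams:
    """Parameters of the synthetic cap and its circulation."""

    center_lon: float = -45.0
    center_lat: float = 47.0
    summit_depth: float = 140.0        # m below surface at the cap summit
    abyss_depth: float = 4000.0        # m in the far field
    cap_radius_km: float = 160.0       # e-folding radius of the Gaussian cap
    jet_core_isobath_m: float = 1700.0 # seafloor depth of peak slope-jet speed
    jet_width_m: float = 700.0         # isobath-space Gaussian width of jet
    jet_peak_speed: float = 0.30       # m/s
    w_downwelling_peak: float = -3.0e-4  # m/s (negative = downward)
    w_upwelling_peak: float = 1.5e-4     # m/s (positive = upward)
    downwelling_isobath_m: float = 1500.0  # center of the downwelling band
    downwelling_width_m: float = 1100.0    # broad band spanning the deep slope
    upwelling_isobath_m: float = 3600.0    # offshore upwelling band
    upwelling_width_m: float = 300.0
    surface_layer_m: float = 200.0     # w ramps from 0 at surface over this
    seasonal_amplitude: float = 0.3    # fractional monthly modulation
    peak_month: float = 8.0            # month of maximum amplitude (August)
    rotation_sense: str = "clockwise"

    def __post_init__(self):
        if not self.summit_depth < self.abyss_depth:
            raise FieldValidationError("summit_depth must be < abyss_depth")
        if self.jet_peak_speed <= 0:
            raise FieldValidationError("jet_peak_speed must be > 0")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise FieldValidationError("seasonal_amplitude must be in [0, 1)")
        if self.rotation_sense not in ("clockwise", "counterclockwise"):
            raise FieldValidationError(
                f"unknown rotation_sense {self.rotation_sense!r}")

    def isobath_radius_km(self, depth_m: float) -> float:
        """Radius at which the Gaussian seafloor reaches ``depth_m``."""
        frac = (self.abyss_depth - depth_m) / (self.abyss_depth - self.summit_depth)
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"depth {depth_m} outside (summit, abyss)")
        return self.cap_radius_km * math.sqrt(-math.log(frac))


def default_grid(params: CapParams = CapParams(), spacing: float = 0.1,
                 half_width_lon: float = 3.5, half_width_lat: float = 2.5,
                 depths: np.ndarray = DEFAULT_DEPTHS) -> Grid3D:
    """Regular grid centered on the cap, comfortably spanning the slope."""
    lons = np.arange(params.center_lon - half_width_lon,
                     params.center_lon + half_width_lon + spacing / 2, spacing)
    lats = np.arange(params.center_lat - half_width_lat,
                     params.center_lat + half_width_lat + spacing / 2, spacing)
    return Grid3D(lons, lats, np.asarray(depths, dtype=float))


def _radius_km(params: CapParams, lons, lats):
    """Local flat-earth distance (km) of grid nodes from the cap center."""
    lon2, lat2 = np.meshgrid(lons, lats)
    x = (lon2 - params.center_lon) * KM_PER_DEG_LAT * math.cos(
        math.radians(params.center_lat))
    y = (lat2 - params.center_lat) * KM_PER_DEG_LAT
    return np.hypot(x, y)


def make_seamount_bathymetry(params: CapParams, grid: Grid3D) -> Bathymetry:
    """Gaussian cap relief: summit at the center, abyssal plain far away."""
    r = _radius_km(params, grid.lons, grid.lats)
    depth = params.abyss_depth - (params.abyss_depth - params.summit_depth) \
        * np.exp(-(r / params.cap_radius_km) ** 2)
    return Bathymetry(grid.lons, grid.lats, depth)


def _seasonal_factors(params: CapParams) -> np.ndarray:
    m = np.arange(1, 13, dtype=float)
    return 1.0 + params.seasonal_amplitude * np.cos(
        2.0 * math.pi * (m - params.peak_month) / 12.0)


def make_cap_circulation(bathy: Bathymetry, params: CapParams,
                         depths: np.ndarray = DEFAULT_DEPTHS) -> FlowField:
    """Clockwise slope jet + prescribed up/downwelling, 12 monthly slices.

    The horizontal velocity is the curl of a streamfunction psi(H) whose
    contours coincide with isobaths, so the discrete field is non-divergent
    and trajectories shadow depth contours.  d(psi)/dH is a Gaussian bump
    centered on ``jet_core_isobath_m``; speed therefore peaks where the
    seafloor crosses that isobath and vanishes over the flat summit and the
    abyssal plain.
    """
    if not params.summit_depth < params.jet_core_isobath_m < params.abyss_depth:
        raise FieldValidationError(
            "jet_core_isobath_m must lie between summit and abyss depths")
    grid = Grid3D(bathy.lons, bathy.lats, np.asarray(depths, dtype=float))
    H = bathy.seafloor_depth
    sense = 1.0 if params.rotation_sense == "clockwise" else -1.0

    # psi = -sense * integral of exp(-((H - c)/s)^2) dH  (closed form via erf)
    s = params.jet_width_m
    c = params.jet_core_isobath_m
    psi = -sense * s * math.sqrt(math.pi) / 2.0 * erf((H - c) / s)

    # u = -dpsi/dy, v = dpsi/dx with metric spacings in meters
    dy_m = np.gradient(grid.lats) * KM_PER_DEG_LAT * 1e3
    coslat = np.cos(np.radians(grid.lats))[:, None]
    dx_deg = np.gradient(grid.lons)
    dpsi_dy = np.gradient(psi, axis=0) / dy_m[:, None]
    dpsi_dx = np.gradient(psi, axis=1) / (dx_deg[None, :] * KM_PER_DEG_LAT
                                          * 1e3 * coslat)
    u2d = -dpsi_dy
    v2d = dpsi_dx
    speed = np.hypot(u2d, v2d)
    peak = float(speed.max())
    if peak > 0:
        scale = params.jet_peak_speed / peak
        u2d, v2d = u2d * scale, v2d * scale

    # prescribed vertical velocity from the local seafloor depth
    w_iso = (params.w_downwelling_peak
             * np.exp(-((H - params.downwelling_isobath_m)
                        / params.downwelling_width_m) ** 2)
             + params.w_upwelling_peak
             * np.exp(-((H - params.upwelling_isobath_m)
                        / params.upwelling_width_m) ** 2))

    nz, ny, nx = grid.shape
    zshape = np.clip(grid.depths / params.surface_layer_m, 0.0, 1.0)
    u3 = np.broadcast_to(u2d, (nz, ny, nx)).copy()
    v3 = np.broadcast_to(v2d, (nz, ny, nx)).copy()
    w3 = zshape[:, None, None] * w_iso[None, :, :]
    mask = grid.depths[:, None, None] > H[None, :, :]

    fac = _seasonal_factors(params)[:, None, None, None]
    return FlowField(grid,
                     u=fac * u3[None], v=fac * v3[None], w=fac * w3[None],
                     mask=mask)


def make_analytic_flow(kind: str, grid: Grid3D | None = None,
                       u0: float = 0.0, v0: float = 0.0, w0: float = 0.0,
                       omega: float = 1e-4,
                       center_lon: float | None = None,
                       center_lat: float | None = None) -> FlowField:
    """Oracle flows with closed-form trajectories: zero, uniform, solid rotation.

    The default grid sits on the equator, where the lon/lat metric is nearly
    Cartesian and a solid-rotation field integrates to closed circular orbits
    to high accuracy (see docs/methods.md for the metric subtlety at high
    latitude).
    """
    if grid is None:
        # +-0.4 deg keeps |u| = omega * r under the 5 m/s sanity bound for
        # the default rotation rate
        grid = Grid3D(np.arange(-0.4, 0.401, 0.02),
                      np.arange(-0.4, 0.401, 0.02),
                      np.array([0.0, 500.0, 1000.0, 2000.0, 4000.0]))
    nz, ny, nx = grid.shape
    mask = np.zeros((nz, ny, nx), dtype=bool)
    zeros = np.zeros((1, nz, ny, nx))
    if kind == "zero":
        return FlowField(grid, zeros, zeros.copy(), zeros.copy(), mask)
    if kind == "uniform":
        return FlowField(grid, np.full_like(zeros, u0),
                         np.full_like(zeros, v0), np.full_like(zeros, w0), mask)
    if kind == "solid_rotation":
        clon = grid.lons.mean() if center_lon is None else center_lon
        clat = grid.lats.mean() if center_lat is None else center_lat
        lon2, lat2 = np.meshgrid(grid.lons, grid.lats)
        m_per_deg = KM_PER_DEG_LAT * 1e3
        x = (lon2 - clon) * m_per_deg * np.cos(np.radians(lat2))
        y = (lat2 - clat) * m_per_deg
        u2d = -omega * y
        v2d = omega * x
        u3 = np.broadcast_to(u2d, (1, nz, ny, nx))
        v3 = np.broadcast_to(v2d, (1, nz, ny, nx))
        return FlowField(grid, u3.copy(), v3.copy(), zeros.copy(), mask)
    raise ValueError(f"unknown analytic flow kind {kind!r}")


# ---------------------------------------------------------------------------
# hydrography
# ---------------------------------------------------------------------------

def make_ts_climatology(bathy: Bathymetry, params: CapParams = CapParams(),
                        depths: np.ndarray = DEFAULT_DEPTHS,
                        years: int | None = None,
                        noise_std_t: float = 0.05,
                        noise_std_s: float = 0.005,
                        seed: int = 0):
    """(temperature, salinity) monthly climatology, optionally multi-year.

    The vertical structure gives cold (< 4 degC) bottom water below the upper
    slope and salinity rising above 34.8 at depth; a surface-trapped seasonal
    cycle decays over ~60 m.  With ``years`` set, each year receives a single
    Gaussian offset (std ``noise_std_*``), emulating small interannual
    variability around a stable mean state.
    """
    grid = Grid3D(bathy.lons, bathy.lats, np.asarray(depths, dtype=float))
    nz, ny, nx = grid.shape
    z = grid.depths[:, None, None]
    months = np.arange(1, 13, dtype=float)

    t_profile = 2.4 + (12.0 - 2.4) * np.exp(-z / 250.0)       # degC
    s_profile = 34.92 - 0.85 * np.exp(-z / 150.0)             # practical salinity
    t_season = 3.0 * np.cos(2 * math.pi * (months - 8.5) / 12.0)
    s_season = -0.05 * np.cos(2 * math.pi * (months - 8.5) / 12.0)
    zdecay = np.exp(-z / 60.0)

    t_clim = t_profile[None] + t_season[:, None, None, None] * zdecay[None]
    s_clim = s_profile[None] + s_season[:, None, None, None] * zdecay[None]
    t_clim = np.broadcast_to(t_clim, (12, nz, ny, nx)).copy()
    s_clim = np.broadcast_to(s_clim, (12, nz, ny, nx)).copy()
    mask = grid.depths[:, None, None] > bathy.seafloor_depth[None, :, :]

    if years is None:
        return (ScalarField(grid, t_clim, mask, name="temperature"),
                ScalarField(grid, s_clim, mask, name="salinity"))

    rng = np.random.default_rng(seed)
    t_off = rng.normal(0.0, noise_std_t, size=years)
    s_off = rng.normal(0.0, noise_std_s, size=years)
    t_vals = np.concatenate([t_clim + t_off[y] for y in range(years)], axis=0)
    s_vals = np.concatenate([s_clim + s_off[y] for y in range(years)], axis=0)
    year_index = np.repeat(np.arange(years), 12)
    return (ScalarField(grid, t_vals, mask, name="temperature",
                        year_index=year_index),
            ScalarField(grid, s_vals, mask, name="salinity",
                        year_index=year_index))


# ---------------------------------------------------------------------------
# closed areas
# ---------------------------------------------------------------------------

@dataclass
class ClosedArea:
    """One closure: a horizontal polygon plus its seafloor depth range."""

    area_id: int
    polygon: Polygon
    min_depth: float
    max_depth: float
    groups: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.polygon.is_valid or len(self.polygon.exterior.coords) < 4:
            raise FieldValidationError(
                f"area {self.area_id}: polygon must be simple with >= 3 vertices")
        if not self.min_depth < self.max_depth:
            raise FieldValidationError(
                f"area {self.area_id}: min_depth must be < max_depth")


# Protection-group membership by area id.
GROUP_AREAS = {
    "sponges": (1, 2, 3, 4, 5, 6),
    "sea_pens": (2, 7, 8, 9, 10, 11, 12, 14),
    "gorgonians": (2, 4, 5, 13),
}


@dataclass
class ClosedAreaSet:
    """Ordered set of closed areas with protection-group labels."""

    areas: list[ClosedArea]

    def __post_init__(self):
        ids = [a.area_id for a in self.areas]
        if len(set(ids)) != len(ids):
            raise FieldValidationError("area ids must be unique")

    def __len__(self):
        return len(self.areas)

    def __iter__(self):
        return iter(self.areas)

    @property
    def ids(self) -> list[int]:
        return [a.area_id for a in self.areas]

    def by_id(self, area_id: int) -> ClosedArea:
        for a in self.areas:
            if a.area_id == area_id:
                return a
        raise KeyError(area_id)

    def group(self, name: str) -> "ClosedAreaSet":
        return ClosedAreaSet([a for a in self.areas if name in a.groups])

    def to_geojson(self, path) -> None:
        feats = []
        for a in self.areas:
            feats.append({
                "type": "Feature",
                "geometry": mapping(a.polygon),
                "properties": {
                    "area_id": a.area_id,
                    "group": list(a.groups),
                    "min_depth": a.min_depth,
                    "max_depth": a.max_depth,
                },
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh,
                      indent=1)

    @classmethod
    def from_geojson(cls, path) -> "ClosedAreaSet":
        with open(path) as fh:
            fc = json.load(fh)
        areas = []
        for feat in fc["features"]:
            p = feat["properties"]
            groups = p.get("group", [])
            if isinstance(groups, str):
                groups = [groups]
            areas.append(ClosedArea(
                area_id=int(p["area_id"]),
                polygon=shape(feat["geometry"]),
                min_depth=float(p["min_depth"]),
                max_depth=float(p["max_depth"]),
                groups=tuple(groups),
            ))
        return cls(areas)


def _sector_polygon(params: CapParams, r_in_km, r_out_km, az0_deg, az1_deg,
                    n_arc=7) -> Polygon:
    """Annular sector around the cap center, vertices in lon/lat degrees."""
    coslat = math.cos(math.radians(params.center_lat))
    pts = []
    for r, azs in ((r_in_km, np.linspace(az0_deg, az1_deg, n_arc)),
                   (r_out_km, np.linspace(az1_deg, az0_deg, n_arc))):
        for az in azs:
            a = math.radians(az)
            pts.append((
                params.center_lon + r * math.cos(a) / (KM_PER_DEG_LAT * coslat),
                params.center_lat + r * math.sin(a) / KM_PER_DEG_LAT,
            ))
    return Polygon(pts)


# Layout of the 14 synthetic closures: (isobath band [m], azimuth span [deg]).
# Azimuth is counterclockwise from east; the clockwise jet carries particles
# toward *decreasing* azimuth, so e.g. area 6 (az 150-180) is upstream of 5,
# 4, 3, 2, 1 — reproducing the downstream chain of the sponge network.  Two
# radially separated rings keep the polygons pairwise disjoint: sea-pen areas
# sit on the upper slope (shallow ring), sponge/gorgonian areas on the deep
# slope, with areas 7 and 14 confined above the ~700 m isobath.
_AREA_LAYOUT = {
    #  id: (depth_in, depth_out, az0, az1)
    1:  (950.0, 2000.0, -50.0, -22.0),
    2:  (490.0, 2150.0, -15.0, 25.0),     # large full-depth downstream wedge
    3:  (950.0, 2000.0, 30.0, 60.0),
    4:  (950.0, 2760.0, 70.0, 100.0),     # the deepest closure
    5:  (950.0, 2400.0, 110.0, 140.0),
    6:  (950.0, 2000.0, 150.0, 180.0),
    7:  (500.0, 700.0, 190.0, 215.0),     # shallow: almost closed to 1000 m
    8:  (520.0, 900.0, 150.0, 175.0),
    9:  (520.0, 900.0, 110.0, 135.0),
    10: (500.0, 880.0, 70.0, 95.0),
    11: (500.0, 880.0, 35.0, 60.0),
    12: (500.0, 880.0, -90.0, -65.0),
    13: (950.0, 1900.0, 210.0, 240.0),
    14: (500.0, 690.0, -55.0, -30.0),     # shallow
}


def make_closed_areas(params: CapParams, bathy: Bathymetry) -> ClosedAreaSet:
    """Fourteen annular-sector stand-ins for the real closure polygons.

    Geometric fixtures only — real closure coordinates can be supplied via
    GeoJSON instead.  Seafloor depth ranges are measured from the supplied
    bathymetry over each polygon.
    """
    areas = []
    for aid, (d_in, d_out, az0, az1) in _AREA_LAYOUT.items():
        r_in = params.isobath_radius_km(d_in)
        r_out = params.isobath_radius_km(d_out)
        poly = _sector_polygon(params, r_in, r_out, az0, az1)
        xs, ys = zip(*poly.exterior.coords)
        depths = bathy.depth_at(np.array(xs), np.array(ys))
        cx, cy = poly.centroid.x, poly.centroid.y
        depths = np.append(depths, bathy.depth_at(cx, cy))
        depths = depths[np.isfinite(depths)]
        groups = tuple(g for g, ids in GROUP_AREAS.items() if aid in ids)
        areas.append(ClosedArea(
            area_id=aid, polygon=poly,
            min_depth=float(depths.min()), max_depth=float(depths.max()),
            groups=groups))
    areas.sort(key=lambda a: a.area_id)
    return ClosedAreaSet(areas)
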