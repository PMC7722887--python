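"""Uniform particle seeding over polygons or the whole domain.

Seeds are laid on a fixed angular lattice anchored at the polygon
bounding-box minimum with half-open inclusion [min, max): a 1 x 1 degree
rectangle at 0.01 degree spacing yields exactly 100 x 100 = 10 000 seeds,
and halving the spacing quadruples the count (up to edge effects).  Points
where the seafloor is shallower than the release depth are excluded, so the
seed count decreases with release depth over sloping topography, mirroring
the depth-dependent release counts of the tracking experiments.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .grid_flow import Bathymetry
from .tracker import ParticleState

__all__ = [
    "EmptySeedWarning",
    "seed_polygon",
    "seed_domain",
    "lattice_points",
    "RELEASE_DEPTH_PRESETS",
    "DURATION_PRESETS_DAYS",
]

# Release-depth presets (m) of the three experiment families.
RELEASE_DEPTH_PRESETS = {
    "vertical_movement": (0.0, 100.0, 450.0, 1000.0, 2250.0),
    "source_populations": (1000.0,),
    "sponges": (1245.0, 1422.0, 1684.0),
    "sea_pens": (643.0, 902.0, 1062.0),
    "gorgonians": (643.0, 1245.0, 1684.0),
}

# Drift-duration presets: 2 weeks, 1 month, 3 months.
DURATION_PRESETS_DAYS = (14.0, 30.0, 90.0)


class EmptySeedWarning(UserWarning):
    """A seeding call produced no particles (e.g. release depth too deep)."""


def lattice_points(lon_min: float, lon_max: float, lat_min: float,
                   lat_max: float, spacing: float):
    """Half-open lattice {min + i*s : min + i*s < max} on both axes."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    # tolerate float noise so an exact multiple of the spacing is half-open
    nlon = int(np.ceil((lon_max - lon_min) / spacing - 1e-9))
    nlat = int(np.ceil((lat_max - lat_min) / spacing - 1e-9))
    lons = lon_min + spacing * np.arange(max(nlon, 0))
    lats = lat_min + spacing * np.arange(max(nlat, 0))
    lon2, lat2 = np.meshgrid(lons, lats)
    return lon2.ravel(), lat2.ravel()


def seed_polygon(polygon: Polygon, spacing: float, release_depth,
                 bathy: Bathymetry | None = None,
                 area_id: int = -1,
                 release_time: float = 0.0) -> list[ParticleState]:
    """Lattice seeds inside a polygon at one release depth.

    ``release_depth`` may be a depth in meters or ``"bottom"``, which places
    each particle on the local seafloor.  Lattice points whose seafloor is
    shallower than the release depth (or which lie over land) are excluded.
    Returns a possibly empty list; emptiness raises :class:`EmptySeedWarning`
    as a warning, not an error.
    """
    lon_min, lat_min, lon_max, lat_max = polygon.bounds
    lons, lats = lattice_points(lon_min, lon_max, lat_min, lat_max, spacing)
    if len(lons):
        shapely.prepare(polygon)
        keep = shapely.intersects_xy(polygon, lons, lats)
        lons, lats = lons[keep], lats[keep]

    on_bottom = isinstance(release_depth, str)
    if on_bottom and release_depth != "bottom":
        raise ValueError(f"unknown release depth {release_depth!r}")

    if bathy is not None and len(lons):
        sf = bathy.depth_at(lons, lats)
        ocean = np.isfinite(sf)
        if on_bottom:
            keep = ocean
            depths = np.where(ocean, sf, np.nan)
        else:
            keep = ocean & (sf >= float(release_depth))
            depths = np.full(lons.shape, float(release_depth))
        lons, lats, depths = lons[keep], lats[keep], depths[keep]
    elif on_bottom:
        raise ValueError('release_depth="bottom" requires a bathymetry')
    else:
        depths = np.full(lons.shape, float(release_depth))

    if len(lons) == 0:
        warnings.warn(
            f"seeding produced no particles (area_id={area_id}, "
            f"release_depth={release_depth})", EmptySeedWarning)
    return [
        ParticleState(lon=float(lo), lat=float(la), depth=float(d),
                      area_id=area_id, release_time=release_time)
        for lo, la, d in zip(lons, lats, depths)
    ]


def seed_domain(spacing: float, release_depth, bathy: Bathymetry,
                domain_box: Sequence[float],
                release_time: float = 0.0) -> list[ParticleState]:
    """Uniform seeding over the whole domain box (clipped to the bathymetry)."""
    lon0 = max(domain_box[0], bathy.lons[0])
    lon1 = min(domain_box[1], bathy.lons[-1])
    lat0 = max(domain_box[2], bathy.lats[0])
    lat1 = min(domain_box[3], bathy.lats[-1])
    return seed_polygon(box(lon0, lat0, lon1, lat1), spacing, release_depth,
                        bathy, area_id=-1, release_time=release_time)


def seed_area_set(areas, spacing: float, release_depth,
                  bathy: Bathymetry | None = None,
                  release_time: float = 0.0) -> list[ParticleState]:
    """Seed every area of a :class:`ClosedAreaSet`, tagging source area ids."""
    seeds: list[ParticleState] = []
    for area in areas:
        seeds.extend(seed_polygon(area.polygon, spacing, release_depth,
                                  bathy, area_id=area.area_id,
                                  release_time=release_time))
    return seeds
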