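"""Water-mass characterization: regridding, per-area bottom T/S series and
along-trajectory sampling.

Bottom values are taken at the deepest unmasked level of each grid column
(no vertical extrapolation).  Per-area annual tables average bottom values
over all in-area columns and all 12 months of each year, also reporting the
min/max range within the year.  Along-pathway statistics use the population
(N-denominator) standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .grid_flow import (
    Grid3D,
    OutOfDomainError,
    ScalarField,
    sample_scalar_arrays,
)
from .synthetic_ocean import ClosedAreaSet
from .tracker import SECONDS_PER_MONTH, TrajectorySet

__all__ = ["regrid_linear", "area_bottom_series", "track_ts"]


def regrid_linear(field: ScalarField, target_spacing: float = 0.03,
                  bounds: tuple[float, float, float, float] | None = None
                  ) -> ScalarField:
    """Bilinear horizontal regrid onto a finer regular grid.

    Mask propagates: a target node depending on any masked source cell is
    masked (no renormalization), so regridded averages never draw on land or
    sub-seabed values.  The vertical and time axes are untouched.
    """
    if bounds is None:
        bounds = (field.grid.lons[0], field.grid.lons[-1],
                  field.grid.lats[0], field.grid.lats[-1])
    lon0, lon1, lat0, lat1 = bounds
    if (lon0 < field.grid.lons[0] - 1e-9 or lon1 > field.grid.lons[-1] + 1e-9
            or lat0 < field.grid.lats[0] - 1e-9
            or lat1 > field.grid.lats[-1] + 1e-9):
        raise OutOfDomainError("target grid extends beyond the source grid")
    nlon = int(np.floor((lon1 - lon0) / target_spacing + 1e-9)) + 1
    nlat = int(np.floor((lat1 - lat0) / target_spacing + 1e-9)) + 1
    tlons = lon0 + target_spacing * np.arange(nlon)
    tlats = lat0 + target_spacing * np.arange(nlat)
    grid = Grid3D(tlons, tlats, field.grid.depths)

    src = np.where(field.mask[None], np.nan, field.values)
    nt, nz = field.values.shape[:2]
    out = np.empty((nt, nz, nlat, nlon))
    ix = np.searchsorted(field.grid.lons, tlons, side="right") - 1
    ix = np.clip(ix, 0, len(field.grid.lons) - 2)
    fx = (tlons - field.grid.lons[ix]) / np.diff(field.grid.lons)[ix]
    iy = np.searchsorted(field.grid.lats, tlats, side="right") - 1
    iy = np.clip(iy, 0, len(field.grid.lats) - 2)
    fy = (tlats - field.grid.lats[iy]) / np.diff(field.grid.lats)[iy]
    for t in range(nt):
        for k in range(nz):
            plane = src[t, k]
            # NaN propagation implements strict mask handling
            out[t, k] = ((1 - fy)[:, None] * ((1 - fx) * plane[np.ix_(iy, ix)]
                                              + fx * plane[np.ix_(iy, ix + 1)])
                         + fy[:, None] * ((1 - fx) * plane[np.ix_(iy + 1, ix)]
                                          + fx * plane[np.ix_(iy + 1, ix + 1)]))
    mask = ~np.isfinite(out[0])
    return ScalarField(grid, np.nan_to_num(out), mask, name=field.name,
                       year_index=field.year_index)


def _bottom_plane(field: ScalarField) -> np.ndarray:
    """(time, lat, lon) array of deepest-unmasked-level values; NaN on land."""
    nt, nz, ny, nx = field.values.shape
    ok = ~field.mask
    any_ok = ok.any(axis=0)
    # deepest unmasked level index per column
    kbot = nz - 1 - np.argmax(ok[::-1], axis=0)
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    plane = field.values[:, kbot, jj, ii]
    plane = np.where(any_ok[None], plane, np.nan)
    return plane


def area_bottom_series(temperature: ScalarField, salinity: ScalarField,
                       areas: ClosedAreaSet) -> pd.DataFrame:
    """Per area and year: mean/min/max of bottom temperature and salinity.

    Averages are unweighted over all in-area grid columns and the 12 months
    of the year.  Areas containing no ocean column are flagged with a row of
    NaNs and ``n_columns == 0``.
    """
    if temperature.values.shape != salinity.values.shape:
        raise ValueError("temperature and salinity must share a grid/time axis")
    nt = temperature.n_times
    if nt % 12:
        raise ValueError("need whole years of monthly data")
    year_index = (temperature.year_index if temperature.year_index is not None
                  else np.repeat(np.arange(nt // 12), 12))

    t_bot = _bottom_plane(temperature)
    s_bot = _bottom_plane(salinity)
    lon2, lat2 = np.meshgrid(temperature.grid.lons, temperature.grid.lats)

    rows = []
    for area in areas:
        poly = area.polygon
        shapely.prepare(poly)
        in_area = shapely.intersects_xy(poly, lon2.ravel(), lat2.ravel())
        in_area = in_area.reshape(lon2.shape) & np.isfinite(t_bot[0])
        for year in np.unique(year_index):
            tsel = year_index == year
            if not np.any(in_area):
                rows.append(dict(area_id=area.area_id, year=int(year),
                                 n_columns=0, T_mean=np.nan, T_min=np.nan,
                                 T_max=np.nan, S_mean=np.nan, S_min=np.nan,
                                 S_max=np.nan))
                continue
            tv = t_bot[tsel][:, in_area]
            sv = s_bot[tsel][:, in_area]
            rows.append(dict(
                area_id=area.area_id, year=int(year),
                n_columns=int(np.sum(in_area)),
                T_mean=float(tv.mean()), T_min=float(tv.min()),
                T_max=float(tv.max()),
                S_mean=float(sv.mean()), S_min=float(sv.min()),
                S_max=float(sv.max())))
    return pd.DataFrame(rows)


def track_ts(traj: TrajectorySet, temperature: ScalarField,
             salinity: ScalarField) -> pd.DataFrame:
    """Mean and population std of T/S sampled along each source area's paths.

    Every recorded in-domain position is sampled at its climatological time;
    grounded/out-of-grid samples are skipped.  Returns one row per source
    area (area_id -1 collects untagged particles).
    """
    n, n_rec = traj.lon.shape
    sign = traj.config.sign
    t_months = (traj.release_time + sign * traj.times / SECONDS_PER_MONTH) % 12.0
    valid = np.isfinite(traj.lon)

    t_samp = np.full((n, n_rec), np.nan)
    s_samp = np.full((n, n_rec), np.nan)
    for r in range(n_rec):
        sel = valid[:, r]
        if not np.any(sel):
            continue
        tv, st1 = sample_scalar_arrays(
            temperature, traj.lon[sel, r], traj.lat[sel, r],
            traj.depth[sel, r], t_months[r])
        sv, st2 = sample_scalar_arrays(
            salinity, traj.lon[sel, r], traj.lat[sel, r],
            traj.depth[sel, r], t_months[r])
        tv[st1 != 0] = np.nan
        sv[st2 != 0] = np.nan
        t_samp[sel, r] = tv
        s_samp[sel, r] = sv

    rows = []
    for src in np.unique(traj.source_area):
        sel = traj.source_area == src
        tvals = t_samp[sel][np.isfinite(t_samp[sel])]
        svals = s_samp[sel][np.isfinite(s_samp[sel])]
        rows.append(dict(
            area_id=int(src), n_samples=int(tvals.size),
            T_mean=float(tvals.mean()) if tvals.size else np.nan,
            T_std=float(tvals.std()) if tvals.size else np.nan,
            S_mean=float(svals.mean()) if svals.size else np.nan,
            S_std=float(svals.std()) if svals.size else np.nan))
    return pd.DataFrame(rows)
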