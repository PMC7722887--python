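"""Gridded 3-D ocean fields: containers, NetCDF I/O and space-time interpolation.

Containers hold climatological-monthly velocity (``FlowField``), scalar
hydrography (``ScalarField``) and seafloor depth (``Bathymetry``) on a regular
longitude/latitude/depth grid.  Conventions used throughout the package:

* longitudes are degrees east in [-180, 180), latitudes degrees north, both
  strictly increasing;
* depth is meters below the surface, positive down, ``depths[0] >= 0``;
* vertical velocity ``w`` is positive **up**, so downward motion has w < 0;
* array axis order is (time, depth, lat, lon);
* masked cells (land / below the seabed) carry NaN sentinels, never zeros.

Interpolation is trilinear in space and linear in time between adjacent
climatological months (December wraps to January).  Weights of masked
neighbors are renormalized over the unmasked ones so that velocities are not
artificially damped next to the seabed; a point whose eight spatial neighbors
are all masked yields a *grounded* signal, distinct from the *out-of-domain*
signal raised outside the horizontal grid box.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import xarray as xr

__all__ = [
    "Grid3D",
    "FlowField",
    "ScalarField",
    "Bathymetry",
    "FieldFormatError",
    "FieldValidationError",
    "OutOfDomainError",
    "GroundedError",
    "SAMPLE_OK",
    "SAMPLE_OUT_OF_DOMAIN",
    "SAMPLE_GROUNDED",
    "sample_velocity",
    "sample_velocity_arrays",
    "sample_scalar",
    "sample_scalar_arrays",
    "bottom_value",
    "read_field_netcdf",
    "write_field_netcdf",
]

NETCDF_ENGINE = "scipy"  # NetCDF-3 classic; portable, pure-scipy backend

# Sampling status codes (vectorized API).
SAMPLE_OK = 0
SAMPLE_OUT_OF_DOMAIN = 1
SAMPLE_GROUNDED = 2


class FieldFormatError(ValueError):
    """A NetCDF file does not have the coordinates/variables expected."""


class FieldValidationError(ValueError):
    """A field object violates its structural invariants."""


class OutOfDomainError(RuntimeError):
    """Sample point lies outside the horizontal grid bounding box."""


class GroundedError(RuntimeError):
    """All spatial neighbors of the sample point are masked (land/seabed)."""


def _check_axis(name: str, ax: np.ndarray) -> np.ndarray:
    ax = np.asarray(ax, dtype=float)
    if ax.ndim != 1 or ax.size < 2:
        raise FieldValidationError(f"axis {name!r} must be 1-D with >= 2 points")
    if not np.all(np.isfinite(ax)):
        raise FieldValidationError(f"axis {name!r} contains non-finite values")
    if not np.all(np.diff(ax) > 0):
        raise FieldValidationError(f"axis {name!r} must be strictly increasing")
    return ax


@dataclass(frozen=True)
class Grid3D:
    """Regular lon/lat/depth grid (degrees east, degrees north, m down)."""

    lons: np.ndarray
    lats: np.ndarray
    depths: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lons", _check_axis("lons", self.lons))
        object.__setattr__(self, "lats", _check_axis("lats", self.lats))
        object.__setattr__(self, "depths", _check_axis("depths", self.depths))
        if self.depths[0] < 0:
            raise FieldValidationError("depths[0] must be >= 0 (positive down)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.depths), len(self.lats), len(self.lons)

    def horizontal_box(self) -> tuple[float, float, float, float]:
        return (self.lons[0], self.lons[-1], self.lats[0], self.lats[-1])


def _check_field_arrays(grid, nt, arrays: dict[str, np.ndarray], mask):
    nz, ny, nx = grid.shape
    want = (nt, nz, ny, nx)
    for name, arr in arrays.items():
        if arr.shape != want:
            raise FieldValidationError(
                f"{name} has shape {arr.shape}, expected {want}"
            )
    if mask.shape != (nz, ny, nx):
        raise FieldValidationError(
            f"mask has shape {mask.shape}, expected {(nz, ny, nx)}"
        )


@dataclass
class FlowField:
    """Climatological velocity (u, v east/north m/s; w positive-up m/s).

    ``u``/``v``/``w`` have shape (n_time, n_depth, n_lat, n_lon) with
    ``n_time`` either 12 (months 1..12) or 1 (a steady field, e.g. a
    seasonal or annual mean).  ``mask`` is static (depth, lat, lon), True
    where the cell is land or below the seabed.
    """

    grid: Grid3D
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    mask: np.ndarray

    U_MAX = 5.0    # m/s sanity bound for |u|, |v|
    W_MAX = 0.1    # m/s sanity bound for |w|

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.u.ndim != 4 or self.u.shape[0] not in (1, 12):
            raise FieldValidationError(
                "velocity arrays must be (time, depth, lat, lon) with 1 or 12 "
                f"time slices, got {self.u.shape}"
            )
        _check_field_arrays(self.grid, self.u.shape[0],
                            {"u": self.u, "v": self.v, "w": self.w}, self.mask)
        sea = ~self.mask[None, ...] & np.isfinite(self.u)
        for name, arr, bound in (("u", self.u, self.U_MAX),
                                 ("v", self.v, self.U_MAX),
                                 ("w", self.w, self.W_MAX)):
            if np.any(np.abs(np.where(sea, arr, 0.0)) > bound):
                raise FieldValidationError(
                    f"|{name}| exceeds the sanity bound {bound} m/s"
                )

    @property
    def n_months(self) -> int:
        return self.u.shape[0]

    def time_mean(self, months: Sequence[int] | None = None) -> "FlowField":
        """Steady field: mean of the given months (1-based; default all)."""
        if self.n_months == 1:
            return self
        idx = (np.arange(12) if months is None
               else np.asarray([int(m) - 1 for m in months]))
        return FlowField(
            grid=self.grid,
            u=self.u[idx].mean(axis=0, keepdims=True),
            v=self.v[idx].mean(axis=0, keepdims=True),
            w=self.w[idx].mean(axis=0, keepdims=True),
            mask=self.mask,
        )


@dataclass
class ScalarField:
    """Gridded scalar (temperature in deg C or practical salinity).

    The time axis is either climatological months (nt == 12, or 1 for a
    steady mean) or a multi-year monthly series (nt == 12 * n_years, with
    ``year_index`` giving the year of each slice).
    """

    grid: Grid3D
    values: np.ndarray
    mask: np.ndarray
    name: str = "temperature"
    year_index: np.ndarray | None = None

    BOUNDS = {"temperature": (-2.0, 30.0), "salinity": (0.0, 40.0)}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 4:
            raise FieldValidationError("values must be (time, depth, lat, lon)")
        _check_field_arrays(self.grid, self.values.shape[0],
                            {"values": self.values}, self.mask)
        lo, hi = self.BOUNDS.get(self.name, (-np.inf, np.inf))
        sea = ~self.mask[None, ...] & np.isfinite(self.values)
        vals = np.where(sea, self.values, 0.5 * (lo + hi))
        if np.any(vals < lo) or np.any(vals > hi):
            raise FieldValidationError(
                f"{self.name} values outside the physical range [{lo}, {hi}]"
            )
        if self.year_index is not None:
            self.year_index = np.asarray(self.year_index, dtype=int)
            if self.year_index.shape != (self.values.shape[0],):
                raise FieldValidationError("year_index length must match time axis")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]


@dataclass
class Bathymetry:
    """Seafloor depth (m, positive down) on the horizontal grid; NaN = land."""

    lons: np.ndarray
    lats: np.ndarray
    seafloor_depth: np.ndarray

    def __post_init__(self):
        self.lons = _check_axis("lons", self.lons)
        self.lats = _check_axis("lats", self.lats)
        self.seafloor_depth = np.asarray(self.seafloor_depth, dtype=float)
        if self.seafloor_depth.shape != (len(self.lats), len(self.lons)):
            raise FieldValidationError("seafloor_depth must be (lat, lon)")
        ocean = np.isfinite(self.seafloor_depth)
        if np.any(self.seafloor_depth[ocean] <= 0):
            raise FieldValidationError("ocean seafloor depth must be > 0")

    def depth_at(self, lon, lat):
        """Bilinear seafloor depth at (lon, lat); NaN over land or outside.

        Weights of land (NaN) corners are renormalized over ocean corners so
        coastal cells still report a depth; all-land neighborhoods give NaN.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        scalar = lon.ndim == 0
        lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
        ix, fx, okx = _bracket(self.lons, lon)
        iy, fy, oky = _bracket(self.lats, lat)
        acc = np.zeros(lon.shape)
        wacc = np.zeros(lon.shape)
        for dy in (0, 1):
            wy = np.where(dy == 0, 1.0 - fy, fy)
            for dx in (0, 1):
                wx = np.where(dx == 0, 1.0 - fx, fx)
                vals = self.seafloor_depth[iy + dy, ix + dx]
                w = wy * wx * np.isfinite(vals)
                acc += w * np.nan_to_num(vals)
                wacc += w
        out = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), np.nan)
        out = np.where(okx & oky, out, np.nan)
        return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# interpolation kernel
# ---------------------------------------------------------------------------

def _bracket(axis: np.ndarray, x: np.ndarray):
    """Bracketing index, fraction and inside-flag along one axis."""
    i = np.searchsorted(axis, x, side="right") - 1
    i = np.clip(i, 0, len(axis) - 2)
    f = (x - axis[i]) / (axis[i + 1] - axis[i])
    inside = (x >= axis[0]) & (x <= axis[-1])
    return i, f, inside


def _time_weights(nt: int, time_of_year):
    """Indices/weights for linear interpolation between month centers.

    Month m (1..12) is centered at m - 0.5 in fractional-month coordinates;
    December wraps to January.  Steady fields (nt == 1) ignore time.
    """
    if nt == 1:
        z = np.zeros_like(np.asarray(time_of_year, dtype=float), dtype=int)
        return z, z, np.ones_like(z, dtype=float)
    if nt != 12:
        raise FieldValidationError(
            "temporal sampling requires a steady (1) or climatological (12) "
            f"time axis, got {nt} slices"
        )
    s = (np.asarray(time_of_year, dtype=float) - 0.5) % 12.0
    i0 = np.floor(s).astype(int) % 12
    f = s - np.floor(s)
    i1 = (i0 + 1) % 12
    return i0, i1, 1.0 - f


def _trilinear_masked(values3d, mask3d, iz, fz, iy, fy, ix, fx):
    """Masked-renormalized trilinear interpolation at N points.

    Returns (value, weight_sum); weight_sum == 0 means all corners masked.
    """
    acc = np.zeros(ix.shape)
    wacc = np.zeros(ix.shape)
    for dz in (0, 1):
        wz = (1.0 - fz) if dz == 0 else fz
        for dy in (0, 1):
            wy = (1.0 - fy) if dy == 0 else fy
            for dx in (0, 1):
                wx = (1.0 - fx) if dx == 0 else fx
                w = wz * wy * wx
                m = mask3d[iz + dz, iy + dy, ix + dx]
                v = values3d[iz + dz, iy + dy, ix + dx]
                w = np.where(m | ~np.isfinite(v), 0.0, w)
                acc += w * np.nan_to_num(v)
                wacc += w
    return acc, wacc


def _sample_arrays(arrays: Iterable[np.ndarray], mask, grid, lon, lat, depth,
                   time_of_year):
    """Shared vectorized sampler over one or more co-gridded 4-D arrays."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    depth = np.atleast_1d(np.asarray(depth, dtype=float))
    arrays = list(arrays)
    nt = arrays[0].shape[0]

    ix, fx, okx = _bracket(grid.lons, lon)
    iy, fy, oky = _bracket(grid.lats, lat)
    # Vertical positions above the first level or below the last are clamped
    # (surface layer / near-bottom extrapolation by nearest level).
    iz, fz, _ = _bracket(grid.depths, depth)
    fz = np.clip(fz, 0.0, 1.0)

    t0, t1, wt0 = _time_weights(nt, time_of_year)
    t0 = np.broadcast_to(np.atleast_1d(t0), lon.shape)
    t1 = np.broadcast_to(np.atleast_1d(t1), lon.shape)
    wt0 = np.broadcast_to(np.atleast_1d(wt0), lon.shape)

    status = np.where(okx & oky, SAMPLE_OK, SAMPLE_OUT_OF_DOMAIN).astype(np.int8)
    results = []
    wsum_ref = None
    for arr in arrays:
        vals = np.zeros(lon.shape)
        wsum = np.zeros(lon.shape)
        # the mask is static, so both month slices share corner weights
        for tidx, tw in ((t0, wt0), (t1, 1.0 - wt0)):
            if nt == 1:
                acc, wacc = _trilinear_masked(arr[0], mask, iz, fz, iy, fy, ix, fx)
                vals, wsum = acc, wacc
                break
            # gather per-particle month slice: group by unique month index
            acc = np.zeros(lon.shape)
            wacc = np.zeros(lon.shape)
            for m in np.unique(tidx):
                sel = tidx == m
                a, wa = _trilinear_masked(
                    arr[m], mask, iz[sel], fz[sel], iy[sel], fy[sel],
                    ix[sel], fx[sel])
                acc[sel], wacc[sel] = a, wa
            vals = vals + tw * np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1), 0.0)
            wsum = wacc  # static mask: same for both slices
        if nt == 1:
            vals = np.where(wsum > 0, vals / np.where(wsum > 0, wsum, 1), 0.0)
        results.append(vals)
        wsum_ref = wsum
    grounded = (wsum_ref <= 0) & (status == SAMPLE_OK)
    status[grounded] = SAMPLE_GROUNDED
    bad = status != SAMPLE_OK
    for vals in results:
        vals[bad] = np.nan
    return results, status


def sample_velocity_arrays(field: FlowField, lon, lat, depth, time_of_year):
    """Vectorized (u, v, w, status) at N points; NaN where status != OK."""
    (u, v, w), status = _sample_arrays(
        (field.u, field.v, field.w), field.mask, field.grid,
        lon, lat, depth, time_of_year)
    return u, v, w, status


def sample_velocity(field: FlowField, lon, lat, depth, time_of_year):
    """Scalar convenience sampler returning (u, v, w).

    Raises :class:`OutOfDomainError` outside the horizontal grid box and
    :class:`GroundedError` when every spatial neighbor is masked.
    """
    u, v, w, status = sample_velocity_arrays(
        field, [lon], [lat], [depth], time_of_year)
    _raise_for_status(int(status[0]), lon, lat)
    return float(u[0]), float(v[0]), float(w[0])


def sample_scalar_arrays(field: ScalarField, lon, lat, depth, time_of_year):
    (vals,), status = _sample_arrays(
        (field.values,), field.mask, field.grid, lon, lat, depth, time_of_year)
    return vals, status


def sample_scalar(field: ScalarField, lon, lat, depth, time_of_year):
    vals, status = sample_scalar_arrays(field, [lon], [lat], [depth], time_of_year)
    _raise_for_status(int(status[0]), lon, lat)
    return float(vals[0])


def _raise_for_status(status: int, lon, lat):
    if status == SAMPLE_OUT_OF_DOMAIN:
        raise OutOfDomainError(f"point ({lon}, {lat}) outside the grid box")
    if status == SAMPLE_GROUNDED:
        raise GroundedError(f"point ({lon}, {lat}) has no unmasked neighbors")


def bottom_value(field: ScalarField, lon, lat, time_of_year):
    """Value at the deepest unmasked level of the nearest grid column."""
    i = int(np.argmin(np.abs(field.grid.lons - lon)))
    j = int(np.argmin(np.abs(field.grid.lats - lat)))
    col_ok = ~field.mask[:, j, i] & np.isfinite(field.values[0, :, j, i])
    if not np.any(col_ok):
        raise GroundedError(f"column nearest ({lon}, {lat}) is fully masked")
    k = int(np.max(np.nonzero(col_ok)[0]))
    t0, t1, wt0 = _time_weights(field.n_times, time_of_year)
    v0 = field.values[int(t0), k, j, i]
    v1 = field.values[int(t1), k, j, i]
    return float(wt0 * v0 + (1.0 - wt0) * v1)


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style axis names lon/lat/depth/time)
# ---------------------------------------------------------------------------

_LON_NAMES = ("lon", "longitude", "nav_lon", "x")
_LAT_NAMES = ("lat", "latitude", "nav_lat", "y")
_DEPTH_NAMES = ("depth", "deptht", "z", "lev")
_TIME_NAMES = ("time", "month", "t")


def _find_coord(ds: xr.Dataset, names, required, kind_label):
    for n in names:
        if n in ds.coords or n in ds.variables:
            return n
    if required:
        raise FieldFormatError(
            f"file is missing a {kind_label} coordinate (looked for {names})")
    return None


def _ascending(ds: xr.Dataset, name: str) -> xr.Dataset:
    vals = np.asarray(ds[name].values, dtype=float)
    if vals.ndim != 1:
        raise FieldFormatError(f"coordinate {name!r} must be 1-D")
    d = np.diff(vals)
    if np.all(d > 0):
        return ds
    if np.all(d < 0):
        return ds.isel({name: slice(None, None, -1)})
    raise FieldFormatError(f"coordinate {name!r} is not monotone")


def write_field_netcdf(field, path) -> None:
    """Write a field object as CF-style NetCDF (fill values where masked)."""
    if not path or not str(path):
        raise IOError("empty output path")
    if isinstance(field, Bathymetry):
        ds = xr.Dataset(
            {"seafloor_depth": (("lat", "lon"), field.seafloor_depth,
                                {"units": "m", "positive": "down"})},
            coords={"lon": ("lon", field.lons, {"units": "degrees_east"}),
                    "lat": ("lat", field.lats, {"units": "degrees_north"})},
        )
    elif isinstance(field, FlowField):
        ds = _grid_dataset(field.grid, field.u.shape[0])
        fill = field.mask[None, ...]
        for name, arr in (("u", field.u), ("v", field.v), ("w", field.w)):
            ds[name] = (("time", "depth", "lat", "lon"),
                        np.where(fill, np.nan, arr), {"units": "m s-1"})
    elif isinstance(field, ScalarField):
        ds = _grid_dataset(field.grid, field.n_times)
        units = "degC" if field.name == "temperature" else "1e-3"
        ds[field.name] = (("time", "depth", "lat", "lon"),
                          np.where(field.mask[None, ...], np.nan, field.values),
                          {"units": units})
        if field.year_index is not None:
            ds["year_index"] = (("time",), field.year_index)
    else:
        raise TypeError(f"cannot write object of type {type(field)!r}")
    ds.to_netcdf(path, engine=NETCDF_ENGINE)


def _grid_dataset(grid: Grid3D, nt: int) -> xr.Dataset:
    return xr.Dataset(coords={
        "time": ("time", np.arange(1, nt + 1, dtype=float),
                 {"units": "climatological_month"}),
        "depth": ("depth", grid.depths, {"units": "m", "positive": "down"}),
        "lat": ("lat", grid.lats, {"units": "degrees_north"}),
        "lon": ("lon", grid.lons, {"units": "degrees_east"}),
    })


def read_field_netcdf(path, kind: str):
    """Read a ``flow``, ``scalar`` or ``bathymetry`` NetCDF file.

    Axis order is normalized to (time, depth, lat, lon) with all axes
    ascending; descending input axes are reordered consistently.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    with xr.open_dataset(path, engine=NETCDF_ENGINE, decode_times=False) as ds:
        ds = ds.load()
    lon_n = _find_coord(ds, _LON_NAMES, True, "longitude")
    lat_n = _find_coord(ds, _LAT_NAMES, True, "latitude")
    ds = _ascending(_ascending(ds, lon_n), lat_n)

    if kind == "bathymetry":
        var = "seafloor_depth" if "seafloor_depth" in ds else None
        if var is None:
            cands = [v for v in ds.data_vars if ds[v].ndim == 2]
            if not cands:
                raise FieldFormatError("no 2-D seafloor variable found")
            var = cands[0]
        arr = ds[var].transpose(lat_n, lon_n).values
        return Bathymetry(ds[lon_n].values, ds[lat_n].values, arr)

    depth_n = _find_coord(ds, _DEPTH_NAMES, True, "depth")
    time_n = _find_coord(ds, _TIME_NAMES, True, "time")
    ds = _ascending(ds, depth_n)
    grid = Grid3D(ds[lon_n].values, ds[lat_n].values, ds[depth_n].values)
    order = (time_n, depth_n, lat_n, lon_n)

    if kind == "flow":
        for v in ("u", "v", "w"):
            if v not in ds:
                raise FieldFormatError(f"flow file is missing variable {v!r}")
        u = ds["u"].transpose(*order).values
        v = ds["v"].transpose(*order).values
        w = ds["w"].transpose(*order).values
        mask = ~np.isfinite(u[0])
        return FlowField(grid, np.nan_to_num(u), np.nan_to_num(v),
                         np.nan_to_num(w), mask)
    if kind == "scalar":
        cands = [v for v in ds.data_vars if ds[v].ndim == 4]
        if not cands:
            raise FieldFormatError("no 4-D scalar variable found")
        name = "temperature" if "temperature" in cands else (
            "salinity" if "salinity" in cands else cands[0])
        vals = ds[name].transpose(*order).values
        mask = ~np.isfinite(vals[0])
        year_index = (ds["year_index"].values
                      if "year_index" in ds.variables else None)
        return ScalarField(grid, np.nan_to_num(vals), mask, name=name,
                           year_index=year_index)
    raise ValueError(f"unknown kind {kind!r}")
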