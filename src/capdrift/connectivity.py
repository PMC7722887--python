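"""Trajectory post-processing: visits, connectivity, TTDs, source maps,
vertical-displacement statistics and seasonal matrix correlation.

Conventions follow the connectivity literature for closed-area networks:

* "passing over" an area is a horizontal-only point-in-polygon test at any
  depth (a depth-aware mode is available behind a flag);
* retention is a particle *terminating* inside its release area, whatever
  happened in between;
* a connectivity entry (s, r) is the percentage of particles released from
  s that passed over or terminated in r, with the diagonal counting
  terminations only (retention);
* transit-time distributions histogram first arrivals per receiving area,
  excluding each particle's own release area, normalized to unit mass;
* "depth reached by the first p% of particles" is the p-th percentile of
  the per-particle extreme-depth distribution (linear interpolation), taken
  on the maximum side toward deeper and on the minimum side toward
  shallower values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .synthetic_ocean import ClosedAreaSet
from .tracker import TrajectorySet

__all__ = [
    "VisitTable",
    "ConnectivityMatrix",
    "TransitTimeDistribution",
    "SourceDensityMap",
    "VerticalStats",
    "detect_visits",
    "connectivity_matrix",
    "transit_time_distribution",
    "source_density_map",
    "vertical_stats",
    "matrix_correlation",
]


@dataclass
class VisitTable:
    """First-arrival times and terminal/source areas for an ensemble.

    ``first_arrival`` is (n_particles, n_areas) seconds since release, NaN
    where the particle never entered the area.  ``terminal`` and ``source``
    hold area ids (-1 = none).
    """

    area_ids: list[int]
    first_arrival: np.ndarray
    terminal: np.ndarray
    source: np.ndarray
    duration_s: float

    def __post_init__(self):
        fa = self.first_arrival
        if np.nanmax(fa, initial=0.0) > self.duration_s + 1e-9:
            raise ValueError("first arrival after the run duration")

    @property
    def n_particles(self) -> int:
        return self.first_arrival.shape[0]

    def visited(self, area_id: int) -> np.ndarray:
        j = self.area_ids.index(area_id)
        return np.isfinite(self.first_arrival[:, j])


def detect_visits(traj: TrajectorySet, areas: ClosedAreaSet,
                  depth_aware: bool = False) -> VisitTable:
    """Point-in-polygon visit detection over every recorded step.

    The containment test is horizontal-only by default ("pass-over"
    semantics); with ``depth_aware=True`` a visit additionally requires the
    particle depth to lie within the area's seafloor depth range.  The
    terminal area comes from the final in-domain position; the source area
    from the tagged seed area when available, otherwise from containment of
    the release position.
    """
    n, n_rec = traj.lon.shape
    valid = np.isfinite(traj.lon)
    flat_lon = np.where(valid, traj.lon, 0.0).ravel()
    flat_lat = np.where(valid, traj.lat, 0.0).ravel()

    area_ids = areas.ids
    first = np.full((n, len(area_ids)), np.nan)
    inside_terminal = np.full((n, len(area_ids)), False)
    flon, flat_, _ = traj.final_positions()

    for j, area in enumerate(areas):
        poly = area.polygon
        shapely.prepare(poly)
        inside = shapely.intersects_xy(poly, flat_lon, flat_lat)
        inside = inside.reshape(n, n_rec) & valid
        if depth_aware:
            ok_depth = (traj.depth >= area.min_depth) & \
                       (traj.depth <= area.max_depth)
            inside &= ok_depth & valid
        any_in = inside.any(axis=1)
        idx = np.argmax(inside, axis=1)
        first[any_in, j] = traj.times[idx[any_in]]
        inside_terminal[:, j] = shapely.intersects_xy(poly, flon, flat_)

    terminal = np.full(n, -1, dtype=int)
    hit = inside_terminal.any(axis=1)
    terminal[hit] = np.asarray(area_ids)[np.argmax(inside_terminal, axis=1)][hit]

    source = traj.source_area.copy()
    untagged = source < 0
    if np.any(untagged):
        for j, area in enumerate(areas):
            poly = area.polygon
            shapely.prepare(poly)
            inside0 = shapely.intersects_xy(
                poly, traj.release_lon[untagged], traj.release_lat[untagged])
            src = source[untagged]
            src[inside0 & (src < 0)] = area_ids[j]
            source[untagged] = src

    return VisitTable(area_ids=list(area_ids), first_arrival=first,
                      terminal=terminal, source=source,
                      duration_s=float(traj.times[-1]))


@dataclass
class ConnectivityMatrix:
    """Source x receiving percentages (and raw counts) of exchanged particles."""

    area_ids: list[int]
    counts: np.ndarray          # (S, R) integer counts
    released: np.ndarray        # (S,) particles released per source
    metadata: dict = dc_field(default_factory=dict)

    @property
    def percent(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 100.0 * self.counts / self.released[:, None]
        return np.where(self.released[:, None] > 0, p, np.nan)

    @property
    def undefined_sources(self) -> list[int]:
        return [a for a, rel in zip(self.area_ids, self.released) if rel == 0]

    def retention(self) -> dict[int, float]:
        p = self.percent
        return {a: float(p[i, i]) for i, a in enumerate(self.area_ids)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent, index=self.area_ids,
                            columns=self.area_ids)


def connectivity_matrix(visits: VisitTable,
                        released_counts: dict[int, int] | None = None,
                        metadata: dict | None = None) -> ConnectivityMatrix:
    """Percentage of particles from each source passing over / ending in each
    receiver; the diagonal counts terminations in the release area (retention).
    """
    ids = visits.area_ids
    n_areas = len(ids)
    counts = np.zeros((n_areas, n_areas), dtype=int)
    released = np.zeros(n_areas, dtype=int)
    for i, s in enumerate(ids):
        from_s = visits.source == s
        released[i] = (released_counts[s] if released_counts is not None
                       else int(np.sum(from_s)))
        for j, rcv in enumerate(ids):
            if rcv == s:
                counts[i, j] = int(np.sum(from_s & (visits.terminal == s)))
            else:
                got = np.isfinite(visits.first_arrival[:, j]) | \
                    (visits.terminal == rcv)
                counts[i, j] = int(np.sum(from_s & got))
    mat = ConnectivityMatrix(area_ids=list(ids), counts=counts,
                             released=released, metadata=metadata or {})
    if mat.undefined_sources:
        warnings.warn(
            f"sources with zero released particles: {mat.undefined_sources}",
            UserWarning)
    return mat


@dataclass
class TransitTimeDistribution:
    """Per receiving area: normalized histogram of first-arrival days."""

    bin_width_days: float
    histograms: dict[int, pd.DataFrame]   # area_id -> (day, count, proportion)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for aid, df in sorted(self.histograms.items()):
            d = df.copy()
            d.insert(0, "area_id", aid)
            frames.append(d)
        if not frames:
            return pd.DataFrame(columns=["area_id", "day", "count", "proportion"])
        return pd.concat(frames, ignore_index=True)


def transit_time_distribution(visits: VisitTable,
                              bin_width_days: float = 1.0
                              ) -> TransitTimeDistribution:
    """First-arrival-day histograms, own-release-area arrivals excluded,
    normalized by total arrivals per receiving area."""
    hists: dict[int, pd.DataFrame] = {}
    for j, rcv in enumerate(visits.area_ids):
        keep = np.isfinite(visits.first_arrival[:, j]) & (visits.source != rcv)
        if not np.any(keep):
            continue
        days = visits.first_arrival[keep, j] / 86400.0
        bins = np.floor(days / bin_width_days).astype(int)
        uniq, counts = np.unique(bins, return_counts=True)
        hists[rcv] = pd.DataFrame({
            "day": uniq * bin_width_days,
            "count": counts,
            "proportion": counts / counts.sum(),
        })
    return TransitTimeDistribution(bin_width_days=bin_width_days,
                                   histograms=hists)


@dataclass
class SourceDensityMap:
    """Binned origins of particles that later entered any closed area."""

    bin_deg: float
    cells: pd.DataFrame        # columns: cell_lon, cell_lat, count, proportion
    total_released: int
    total_qualifying: int

    def count_sum(self) -> int:
        return int(self.cells["count"].sum()) if len(self.cells) else 0


def source_density_map(traj: TrajectorySet, visits: VisitTable,
                       bin_deg: float = 0.1,
                       positions: str = "initial") -> SourceDensityMap:
    """Qualifying (area-visiting) particles binned on a regular lon/lat grid.

    ``positions="initial"`` bins release positions (forward runs);
    ``"final"`` bins terminal positions (the mirrored backward mode).  Cell
    (i, j) covers [i*bin, (i+1)*bin) x [j*bin, (j+1)*bin).
    """
    qualifying = np.isfinite(visits.first_arrival).any(axis=1) | \
        (visits.terminal >= 0)
    if positions == "initial":
        lon, lat = traj.release_lon, traj.release_lat
    elif positions == "final":
        lon, lat, _ = traj.final_positions()
    else:
        raise ValueError(f"unknown positions mode {positions!r}")
    lon, lat = lon[qualifying], lat[qualifying]
    total = traj.n_particles
    nq = int(np.sum(qualifying))
    if nq == 0:
        cells = pd.DataFrame(columns=["cell_lon", "cell_lat", "count",
                                      "proportion"])
        return SourceDensityMap(bin_deg, cells, total, 0)
    ix = np.floor(lon / bin_deg).astype(int)
    iy = np.floor(lat / bin_deg).astype(int)
    df = pd.DataFrame({"ix": ix, "iy": iy})
    g = df.groupby(["ix", "iy"]).size().reset_index(name="count")
    cells = pd.DataFrame({
        "cell_lon": g["ix"] * bin_deg,
        "cell_lat": g["iy"] * bin_deg,
        "count": g["count"],
    })
    cells["proportion"] = cells["count"] / total
    cells = cells.sort_values(["cell_lon", "cell_lat"]).reset_index(drop=True)
    return SourceDensityMap(bin_deg, cells, total, nq)


@dataclass
class VerticalStats:
    """Extreme-depth statistics of an ensemble for one release scenario.

    ``max_p[p]`` is the depth D such that p% of particles have maximum depth
    <= D (p-th percentile of the per-particle maxima); ``min_p[p]`` mirrors
    this on the shallow side: the depth D such that p% of particles have
    minimum depth >= D ((100-p)-th percentile of the minima).
    """

    release_depth: float
    n_particles: int
    min_reached: float
    max_reached: float
    min_p: dict[int, float]
    max_p: dict[int, float]
    degenerate: bool = False

    def ordered(self) -> bool:
        ps = sorted(self.max_p)
        chain_max = [self.max_p[p] for p in ps] + [self.max_reached]
        chain_min = [self.min_p[p] for p in ps] + [self.min_reached]
        return (np.all(np.diff(chain_max) >= -1e-9)
                and np.all(np.diff(chain_min) <= 1e-9))


def vertical_stats(traj: TrajectorySet, release_depth: float | None = None,
                   percentiles=(25, 50, 75)) -> VerticalStats:
    """Per-ensemble extreme depths and their percentile summaries."""
    minima = traj.min_depth
    maxima = traj.max_depth
    n = len(minima)
    degenerate = n < 2
    if degenerate:
        warnings.warn("fewer than 2 particles: percentiles are degenerate",
                      UserWarning)
    if release_depth is None:
        release_depth = float(np.median(traj.release_depth))
    max_p = {int(p): float(np.percentile(maxima, p)) for p in percentiles}
    min_p = {int(p): float(np.percentile(minima, 100 - p))
             for p in percentiles}
    return VerticalStats(
        release_depth=float(release_depth), n_particles=n,
        min_reached=float(minima.min()), max_reached=float(maxima.max()),
        min_p=min_p, max_p=max_p, degenerate=degenerate)


def matrix_correlation(m1: ConnectivityMatrix, m2: ConnectivityMatrix) -> float:
    """Pearson r between two matrices' flattened count vectors."""
    if m1.area_ids != m2.area_ids:
        raise ValueError("matrices cover different area sets")
    a = m1.counts.ravel().astype(float)
    b = m2.counts.ravel().astype(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance count vector: correlation undefined")
    if np.array_equal(a, b):
        return 1.0  # exact self-correlation, no float round-off
    return float(stats.pearsonr(a, b)[0])
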