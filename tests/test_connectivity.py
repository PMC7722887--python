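"""Connectivity statistics against hand examples and a naive reimplementation.

The brute-force oracle below re-derives every statistic with explicit loops
over particles and recorded steps (shapely Point containment, manual
tallies); the vectorized implementations must match it exactly on a
50-particle, 3-area fixture.
"""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from capdrift.connectivity import (
    connectivity_matrix,
    detect_visits,
    matrix_correlation,
    source_density_map,
    transit_time_distribution,
    vertical_stats,
)
from capdrift.synthetic_ocean import ClosedArea, ClosedAreaSet
from capdrift.tracker import TrackerConfig, TrajectorySet


def make_traj(lon, lat, depth=None, dt=1200.0, record_every=1, sources=None,
              K_h=0.0):
    """Assemble a TrajectorySet directly from position arrays."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n, n_rec = lon.shape
    if depth is None:
        depth = np.full((n, n_rec), 500.0)
    depth = np.asarray(depth, dtype=float)
    times = np.arange(n_rec) * dt * record_every
    status = np.where(np.isfinite(lon), 0, 1).astype(np.int8)
    cfg = TrackerConfig(dt=dt, K_h=K_h, record_every=record_every,
                        duration_days=times[-1] / 86400.0 or 1.0)
    with np.errstate(invalid="ignore"):
        min_d = np.nanmin(depth, axis=1)
        max_d = np.nanmax(depth, axis=1)
    return TrajectorySet(
        times=times, lon=lon, lat=lat, depth=depth, status=status,
        release_lon=lon[:, 0].copy(), release_lat=lat[:, 0].copy(),
        release_depth=depth[:, 0].copy(), release_time=0.0,
        source_area=(np.asarray(sources, dtype=int) if sources is not None
                     else np.full(n, -1)),
        min_depth=min_d, max_depth=max_d, config=cfg)


def three_areas():
    return ClosedAreaSet([
        ClosedArea(1, box(0.0, 0.0, 1.0, 1.0), 500.0, 1500.0),
        ClosedArea(2, box(2.0, 0.0, 3.0, 1.0), 500.0, 1500.0),
        ClosedArea(3, box(4.0, 0.0, 5.0, 1.0), 500.0, 1500.0),
    ])


class TestHandExamples:
    def test_first_arrival_time_on_crossing(self):
        # particle crosses area 2 at record k=3 -> arrival = 3 * dt
        lon = np.array([[1.5, 1.7, 1.9, 2.1, 2.5, 3.5]])
        lat = np.full((1, 6), 0.5)
        traj = make_traj(lon, lat)
        visits = detect_visits(traj, three_areas())
        assert visits.first_arrival[0, 1] == pytest.approx(3 * 1200.0)
        assert np.isnan(visits.first_arrival[0, 0])
        assert visits.terminal[0] == -1

    def test_retention_candidate(self):
        lon = np.array([[0.5, 0.6, 0.5]])
        lat = np.full((1, 3), 0.5)
        traj = make_traj(lon, lat, sources=[1])
        visits = detect_visits(traj, three_areas())
        assert visits.terminal[0] == 1
        assert visits.source[0] == 1

    def test_half_visit_rate_is_50_percent(self):
        # 4 particles from area 1, 2 of them reach area 2
        lon = np.array([
            [0.5, 1.5, 2.5],
            [0.5, 1.5, 2.5],
            [0.5, 1.2, 1.4],
            [0.5, 0.6, 0.7],
        ])
        lat = np.full((4, 3), 0.5)
        traj = make_traj(lon, lat, sources=[1, 1, 1, 1])
        mat = connectivity_matrix(detect_visits(traj, three_areas()))
        assert mat.percent[0, 1] == pytest.approx(50.0)

    def test_all_retained_identity_diagonal(self):
        lon = np.array([[0.5, 0.5], [2.5, 2.5], [4.5, 4.5]])
        lat = np.full((3, 2), 0.5)
        traj = make_traj(lon, lat, sources=[1, 2, 3])
        mat = connectivity_matrix(detect_visits(traj, three_areas()))
        assert np.allclose(np.diag(mat.percent), 100.0)
        off = mat.percent[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_ttd_direct_tally(self):
        # arrivals into area 2 at days {2, 2, 4} -> bins {2: 2/3, 4: 1/3}
        steps_per_day = 72
        n_rec = 5 * steps_per_day + 1
        lon = np.full((3, n_rec), 1.5)
        lat = np.full((3, n_rec), 0.5)
        for i, day in enumerate([2, 2, 4]):
            lon[i, day * steps_per_day:] = 2.5
        traj = make_traj(lon, lat, sources=[1, 1, 1])
        ttd = transit_time_distribution(detect_visits(traj, three_areas()))
        h = ttd.histograms[2]
        assert dict(zip(h["day"], h["proportion"])) == \
            {2.0: pytest.approx(2 / 3), 4.0: pytest.approx(1 / 3)}

    def test_ttd_excludes_retention_only_arrivals(self):
        lon = np.array([[0.5, 0.5, 0.5]])
        lat = np.full((1, 3), 0.5)
        traj = make_traj(lon, lat, sources=[1])
        ttd = transit_time_distribution(detect_visits(traj, three_areas()))
        assert ttd.histograms == {}

    def test_source_map_floor_binning(self):
        # two qualifying origins in the same 0.1 deg cell
        lon = np.array([[-45.01, 0.5], [-45.05, 0.5]])
        lat = np.array([[47.02, 0.5], [47.08, 0.5]])
        traj = make_traj(lon, lat)
        visits = detect_visits(traj, three_areas())
        sdm = source_density_map(traj, visits, bin_deg=0.1)
        assert len(sdm.cells) == 1
        assert sdm.cells["count"].iloc[0] == 2
        assert sdm.cells["cell_lon"].iloc[0] == pytest.approx(-45.1)
        assert sdm.cells["cell_lat"].iloc[0] == pytest.approx(47.0)

    def test_source_map_empty_when_no_visits(self):
        lon = np.full((3, 2), -45.0)
        lat = np.full((3, 2), 47.0)
        traj = make_traj(lon, lat)
        visits = detect_visits(traj, three_areas())
        sdm = source_density_map(traj, visits)
        assert sdm.count_sum() == 0

    def test_vertical_percentile_median_example(self):
        # per-particle maxima {110, 120, 130, 900} -> p50 = 125
        depth = np.array([[100.0, 110.0], [100.0, 120.0],
                          [100.0, 130.0], [100.0, 900.0]])
        lon = np.zeros((4, 2))
        lat = np.zeros((4, 2))
        traj = make_traj(lon, lat, depth=depth)
        vs = vertical_stats(traj, release_depth=100.0)
        assert vs.max_p[50] == pytest.approx(125.0)
        assert vs.max_reached == 900.0

    def test_frozen_particles_all_stats_at_release(self):
        depth = np.full((5, 4), 100.0)
        traj = make_traj(np.zeros((5, 4)), np.zeros((5, 4)), depth=depth)
        vs = vertical_stats(traj, release_depth=100.0)
        assert vs.min_reached == vs.max_reached == 100.0
        assert all(v == 100.0 for v in vs.max_p.values())
        assert all(v == 100.0 for v in vs.min_p.values())

    def test_percentile_ordering_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 60)
            depth = rng.uniform(100, 3000, (n, 6))
            traj = make_traj(np.zeros((n, 6)), np.zeros((n, 6)), depth=depth)
            vs = vertical_stats(traj)
            assert vs.ordered()

    def test_matrix_self_correlation_exactly_one(self):
        lon = np.array([[0.5, 1.5, 2.5], [0.5, 0.6, 0.7]])
        lat = np.full((2, 3), 0.5)
        traj = make_traj(lon, lat, sources=[1, 1])
        mat = connectivity_matrix(detect_visits(traj, three_areas()))
        assert matrix_correlation(mat, mat) == 1.0

    def test_matrix_scale_invariance(self):
        lon = np.array([[0.5, 1.5, 2.5], [0.5, 2.5, 4.5], [2.5, 2.6, 2.7]])
        lat = np.full((3, 3), 0.5)
        traj = make_traj(lon, lat, sources=[1, 1, 2])
        m1 = connectivity_matrix(detect_visits(traj, three_areas()))
        import copy
        m2 = copy.deepcopy(m1)
        m2.counts = 2 * m2.counts
        assert matrix_correlation(m1, m2) == pytest.approx(1.0)

    def test_anti_ordered_counts_give_minus_one(self):
        import copy
        lon = np.array([[0.5, 1.5, 2.5]])
        lat = np.full((1, 3), 0.5)
        traj = make_traj(lon, lat, sources=[1])
        m1 = connectivity_matrix(detect_visits(traj, three_areas()))
        m1.counts = np.array([[1, 2], [3, 0]])[:2, :2]
        m2 = copy.deepcopy(m1)
        m1.counts = np.array([[1, 2], [3, 4]])
        m2.counts = np.array([[4, 3], [2, 1]])
        assert matrix_correlation(m1, m2) == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        import copy
        lon = np.array([[0.5, 0.5]])
        lat = np.full((1, 2), 0.5)
        traj = make_traj(lon, lat, sources=[1])
        m1 = connectivity_matrix(detect_visits(traj, three_areas()))
        m2 = copy.deepcopy(m1)
        m1.counts = np.ones((3, 3), dtype=int)
        with pytest.raises(ValueError):
            matrix_correlation(m1, m2)


# ---------------------------------------------------------------------------
# brute-force equivalence
# ---------------------------------------------------------------------------

def naive_statistics(traj, areas, bin_deg=0.1):
    """Loop-based re-derivation of every statistic (the independent oracle)."""
    n, n_rec = traj.lon.shape
    ids = [a.area_id for a in areas]
    polys = {a.area_id: a.polygon for a in areas}

    first = {}
    for i in range(n):
        for aid in ids:
            for r in range(n_rec):
                if not math.isfinite(traj.lon[i, r]):
                    continue
                if polys[aid].intersects(Point(traj.lon[i, r],
                                               traj.lat[i, r])):
                    first[(i, aid)] = traj.times[r]
                    break

    terminal = {}
    for i in range(n):
        last = max(r for r in range(n_rec) if math.isfinite(traj.lon[i, r]))
        for aid in ids:
            if polys[aid].intersects(Point(traj.lon[i, last],
                                           traj.lat[i, last])):
                terminal[i] = aid
                break

    # untagged particles inherit the area containing their release position
    sources = {}
    for i in range(n):
        sources[i] = int(traj.source_area[i])
        if sources[i] < 0:
            for aid in ids:
                if polys[aid].intersects(Point(traj.release_lon[i],
                                               traj.release_lat[i])):
                    sources[i] = aid
                    break

    # connectivity counts
    counts = np.zeros((len(ids), len(ids)), dtype=int)
    released = np.zeros(len(ids), dtype=int)
    for si, s in enumerate(ids):
        for i in range(n):
            if sources[i] != s:
                continue
            released[si] += 1
            for ri, rcv in enumerate(ids):
                if rcv == s:
                    if terminal.get(i) == s:
                        counts[si, ri] += 1
                elif (i, rcv) in first or terminal.get(i) == rcv:
                    counts[si, ri] += 1

    # transit-time histograms
    ttd = {}
    for ri, rcv in enumerate(ids):
        arrivals = [first[(i, rcv)] / 86400.0 for i in range(n)
                    if (i, rcv) in first and sources[i] != rcv]
        if not arrivals:
            continue
        hist = {}
        for day in arrivals:
            b = math.floor(day)
            hist[b] = hist.get(b, 0) + 1
        total = sum(hist.values())
        ttd[rcv] = {b: c / total for b, c in sorted(hist.items())}

    # source-density cells
    cells = {}
    nq = 0
    for i in range(n):
        qual = i in terminal or any((i, aid) in first for aid in ids)
        if not qual:
            continue
        nq += 1
        key = (math.floor(traj.release_lon[i] / bin_deg),
               math.floor(traj.release_lat[i] / bin_deg))
        cells[key] = cells.get(key, 0) + 1

    # vertical percentiles by sorting (median-style linear interpolation)
    maxima = sorted(traj.max_depth)
    minima = sorted(traj.min_depth)

    def pct(sorted_vals, p):
        k = (len(sorted_vals) - 1) * p / 100.0
        f = math.floor(k)
        c = math.ceil(k)
        if f == c:
            return sorted_vals[int(k)]
        return sorted_vals[f] * (c - k) + sorted_vals[c] * (k - f)

    vertical = {
        "max_reached": maxima[-1], "min_reached": minima[0],
        "max_p": {p: pct(maxima, p) for p in (25, 50, 75)},
        "min_p": {p: pct(minima, 100 - p) for p in (25, 50, 75)},
    }
    return dict(first=first, terminal=terminal, counts=counts,
                released=released, ttd=ttd, cells=cells, nq=nq,
                vertical=vertical)


@pytest.fixture(scope="module")
def fixture_50():
    # 50 random-walk trajectories wandering across a 3-area seascape,
    # a few removed mid-run
    rng = np.random.default_rng(42)
    n, n_rec = 50, 40
    lon = np.empty((n, n_rec))
    lat = np.empty((n, n_rec))
    depth = np.empty((n, n_rec))
    lon[:, 0] = rng.uniform(-0.5, 5.5, n)
    lat[:, 0] = rng.uniform(-0.5, 1.5, n)
    depth[:, 0] = rng.uniform(400, 1200, n)
    for r in range(1, n_rec):
        lon[:, r] = lon[:, r - 1] + rng.normal(0.0, 0.15, n)
        lat[:, r] = lat[:, r - 1] + rng.normal(0.0, 0.08, n)
        depth[:, r] = np.clip(depth[:, r - 1] + rng.normal(0, 40, n),
                              0, 3000)
    # remove 5 particles at random times (NaN tails)
    for i in rng.choice(n, 5, replace=False):
        cut = rng.integers(5, n_rec - 2)
        lon[i, cut:] = np.nan
        lat[i, cut:] = np.nan
        depth[i, cut:] = np.nan
    sources = rng.choice([1, 2, 3, -1], n)
    return make_traj(lon, lat, depth=depth, sources=sources)


class TestBruteForceEquivalence:
    def test_all_statistics_match_naive_loops(self, fixture_50):
        areas = three_areas()
        traj = fixture_50
        oracle = naive_statistics(traj, areas)
        visits = detect_visits(traj, areas)

        # first arrivals and terminals
        for i in range(traj.n_particles):
            for j, aid in enumerate(visits.area_ids):
                got = visits.first_arrival[i, j]
                want = oracle["first"].get((i, aid))
                if want is None:
                    assert np.isnan(got)
                else:
                    assert got == want
            assert visits.terminal[i] == oracle["terminal"].get(i, -1)

        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            mat = connectivity_matrix(visits)
        np.testing.assert_array_equal(mat.counts, oracle["counts"])
        np.testing.assert_array_equal(mat.released, oracle["released"])

        ttd = transit_time_distribution(visits)
        assert set(ttd.histograms) == set(oracle["ttd"])
        for aid, want in oracle["ttd"].items():
            h = ttd.histograms[aid]
            got = dict(zip(h["day"], h["proportion"]))
            assert got.keys() == want.keys()
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-12)

        sdm = source_density_map(traj, visits, bin_deg=0.1)
        got_cells = {(round(r.cell_lon / 0.1), round(r.cell_lat / 0.1)):
                     r["count"] for _, r in sdm.cells.iterrows()}
        assert got_cells == oracle["cells"]
        assert sdm.total_qualifying == oracle["nq"]

        vs = vertical_stats(traj)
        want = oracle["vertical"]
        assert vs.max_reached == want["max_reached"]
        assert vs.min_reached == want["min_reached"]
        for p in (25, 50, 75):
            assert vs.max_p[p] == pytest.approx(want["max_p"][p], abs=1e-9)
            assert vs.min_p[p] == pytest.approx(want["min_p"][p], abs=1e-9)


class TestForwardBackwardCounterpart:
    def test_rotation_ring_connections_symmetric(self, rotation_flow):
        """In a steady rotation, a forward connection s->r is recovered by
        backward tracking from r (two areas on the same orbit)."""
        from capdrift.tracker import ParticleState, advect
        from conftest import GLOBE

        r_deg = 10e3 / 111195.0
        # two small boxes on the 10 km orbit, a quarter turn apart
        a_up = ClosedArea(1, box(-0.02, r_deg - 0.02, 0.02, r_deg + 0.02),
                          100.0, 1000.0)
        a_dn = ClosedArea(2, box(-r_deg - 0.02, -0.02, -r_deg + 0.02, 0.02),
                          100.0, 1000.0)
        areas = ClosedAreaSet([a_up, a_dn])
        quarter = (math.pi / 2) / 1e-4 / 86400.0
        cfg = TrackerConfig(dt=1200.0, K_h=0.0,
                            duration_days=math.ceil(quarter * 72) / 72 + 0.1,
                            domain_box=GLOBE)
        fwd = advect([ParticleState(lon=0.0, lat=r_deg, depth=500.0,
                                    area_id=1)], rotation_flow, cfg)
        vf = detect_visits(fwd, areas)
        assert np.isfinite(vf.first_arrival[0, 1])  # 1 -> 2 forward
        bwd = advect([ParticleState(lon=-r_deg, lat=0.0, depth=500.0,
                                    area_id=2)], rotation_flow,
                     TrackerConfig(dt=1200.0, K_h=0.0,
                                   duration_days=cfg.duration_days,
                                   direction="backward", domain_box=GLOBE))
        vb = detect_visits(bwd, areas)
        assert np.isfinite(vb.first_arrival[0, 0])  # 2 <- 1 backward
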