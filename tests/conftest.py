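"""Shared fixtures: a small synthetic ocean and analytic oracle flows."""

import numpy as np
import pytest

from capdrift.synthetic_ocean import (
    CapParams,
    default_grid,
    make_analytic_flow,
    make_cap_circulation,
    make_closed_areas,
    make_seamount_bathymetry,
    make_ts_climatology,
)

# Domain box that never interferes with oracle runs on the equatorial grid.
GLOBE = (-180.0, 180.0, -90.0, 90.0)


@pytest.fixture(scope="session")
def cap_params():
    return CapParams()


@pytest.fixture(scope="session")
def cap_grid(cap_params):
    return default_grid(cap_params)


@pytest.fixture(scope="session")
def bathy(cap_params, cap_grid):
    return make_seamount_bathymetry(cap_params, cap_grid)


@pytest.fixture(scope="session")
def cap_flow(cap_params, bathy, cap_grid):
    return make_cap_circulation(bathy, cap_params, depths=cap_grid.depths)


@pytest.fixture(scope="session")
def steady_cap_flow(cap_flow):
    return cap_flow.time_mean()


@pytest.fixture(scope="session")
def closed_areas(cap_params, bathy):
    return make_closed_areas(cap_params, bathy)


@pytest.fixture(scope="session")
def ts_fields(cap_params, bathy):
    return make_ts_climatology(bathy, cap_params)


@pytest.fixture(scope="session")
def zero_flow():
    return make_analytic_flow("zero")


@pytest.fixture(scope="session")
def rotation_flow():
    return make_analytic_flow("solid_rotation", omega=1e-4)


def seeds_in_band(bathy, depth, h_min, h_max, n, rng_seed=3,
                  box=(-48.5, -41.5, 44.6, 49.4)):
    """Random release positions over seafloor in [h_min, h_max] at one depth."""
    from capdrift.tracker import ParticleState

    rng = np.random.default_rng(rng_seed)
    seeds = []
    while len(seeds) < n:
        lon = rng.uniform(box[0], box[1])
        lat = rng.uniform(box[2], box[3])
        h = bathy.depth_at(lon, lat)
        if np.isfinite(h) and h_min < h < h_max:
            seeds.append(ParticleState(lon=lon, lat=lat, depth=float(depth)))
    return seeds
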