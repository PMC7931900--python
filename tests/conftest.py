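import numpy as np
import pytest

from vegmem.grid import SpatioTemporalCube, TimeAxis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cube(values, start_year=2000, steps_per_year=None, grid_shape=None,
              lat=None, valid=None):
    """Small helper: build a cube from a (pixel, time) array."""
    values = np.asarray(values, dtype=float)
    p, t = values.shape
    spy = steps_per_year if steps_per_year is not None else t
    axis = TimeAxis(start_year, t, spy)
    if lat is None:
        lat = np.linspace(50, -50, p)
    lon = np.linspace(0, 10, p)
    if valid is None:
        valid = np.isfinite(values)
    return SpatioTemporalCube(
        values=np.nan_to_num(values), valid=valid, lat=np.asarray(lat, float),
        lon=lon, time=axis, grid_shape=grid_shape)


@pytest.fixture
def toy_cube():
    """2 pixels x 2 years x 4 steps/year with a known seasonal structure."""
    vals = np.array([
        [1.0, 2.0, 3.0, 4.0, 3.0, 2.0, 5.0, 4.0],
        [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
    ])
    return make_cube(vals, steps_per_year=4)
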