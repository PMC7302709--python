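import numpy as np
import pytest
from shapely.geometry import box

from larvadrift.ocean_field import CurrentField
from larvadrift.seeding import SeedPolygonSet

DX = 1.0 / 12.0


def make_uniform_field(u0=0.0, v0=0.0, nx=60, ny=20, dx=DX, lon0=0.0, lat0=None, n_days=61):
    """Constant-velocity field; latitude band centred on the equator by default."""
    if lat0 is None:
        lat0 = -(ny - 1) * dx / 2.0
    lon = lon0 + dx * np.arange(nx)
    lat = lat0 + dx * np.arange(ny)
    time = np.arange(n_days, dtype=float)
    u = np.full((n_days, ny, nx), float(u0))
    v = np.full((n_days, ny, nx), float(v0))
    return CurrentField(lon_axis=lon, lat_axis=lat, time_axis=time, u=u, v=v)


def make_linear_field(a=0.1, b=-0.05, nx=12, ny=10, dx=DX, lon0=30.0, lat0=-5.0, n_days=4):
    """u = a*lon + b*lat, v = -b*lon + a*lat; bilinear interpolation is exact."""
    lon = lon0 + dx * np.arange(nx)
    lat = lat0 + dx * np.arange(ny)
    glon, glat = np.meshgrid(lon, lat)
    u = np.repeat((a * glon + b * glat)[None], n_days, axis=0)
    v = np.repeat((-b * glon + a * glat)[None], n_days, axis=0)
    return CurrentField(lon_axis=lon, lat_axis=lat, time_axis=np.arange(n_days, dtype=float),
                        u=u, v=v)


def square_polyset(lon0, lat0, side):
    return SeedPolygonSet([box(lon0, lat0, lon0 + side, lat0 + side)])


@pytest.fixture
def uniform_zero_field():
    return make_uniform_field(0.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
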