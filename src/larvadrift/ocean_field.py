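"""Gridded surface-current forcing and space--time velocity interpolation.

The hydrodynamic forcing is a stack of daily surface-velocity snapshots on a
regular lon/lat grid (HYCOM-style: 1/12 degree, daily output).  Only surface
currents are represented; vertical structure, tides and wind are out of scope.
Velocity at an arbitrary particle position and time is obtained by linear
interpolation in time between the two bracketing daily snapshots followed by
bilinear interpolation among the four surrounding grid nodes.  Land nodes
contribute zero velocity to the interpolation weights, which damps the flow
smoothly toward coasts and never manufactures velocities from land data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

#: Metres per degree of latitude on a spherical earth (small-displacement
#: approximation; zonal spacing scales with cos(latitude)).
METERS_PER_DEGREE = 111_320.0

#: Default variable-name map for HYCOM-convention files.
DEFAULT_VARIABLE_NAMES = {
    "lon": "lon",
    "lat": "lat",
    "time": "time",
    "u": "water_u",
    "v": "water_v",
}


class FieldFormatError(ValueError):
    """A forcing file is missing a variable or axis."""


class FieldValidationError(ValueError):
    """Axes or velocities violate the forcing-grid invariants."""


class OutOfDomainError(ValueError):
    """A velocity query fell outside the spatial or temporal grid extent."""


def _check_uniform(axis: np.ndarray, name: str) -> float:
    if axis.ndim != 1 or axis.size < 2:
        raise FieldValidationError(f"{name} axis must be 1-D with >= 2 nodes")
    d = np.diff(axis)
    if np.any(d <= 0):
        raise FieldValidationError(f"{name} axis must be strictly increasing")
    step = d[0]
    if not np.allclose(d, step, rtol=1e-9, atol=0.0):
        raise FieldValidationError(f"{name} axis spacing is not uniform")
    return float(step)


@dataclass
class CurrentField:
    """Gridded daily surface velocities with a land mask.

    Parameters
    ----------
    lon_axis, lat_axis
        Node coordinates in degrees east / north, strictly increasing with
        uniform spacing.
    time_axis
        Days since the simulation origin, integer daily steps.
    u, v
        Eastward / northward surface velocity in m s^-1 with dimensions
        (time, lat, lon).  Land nodes may hold NaN.
    land_mask
        Boolean per (lat, lon) node, True = land / invalid.  If omitted it is
        derived from non-finite velocity nodes.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    time_axis: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray | None = None

    dx_deg: float = field(init=False)
    dy_deg: float = field(init=False)

    def __post_init__(self) -> None:
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)

        self.dx_deg = _check_uniform(self.lon_axis, "lon")
        self.dy_deg = _check_uniform(self.lat_axis, "lat")
        _check_uniform(self.time_axis, "time")

        shape = (self.time_axis.size, self.lat_axis.size, self.lon_axis.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise FieldValidationError(
                f"velocity shape {self.u.shape} does not match (time, lat, lon) {shape}"
            )

        bad = ~np.isfinite(self.u) | ~np.isfinite(self.v)
        derived_mask = bad.any(axis=0)
        if self.land_mask is None:
            self.land_mask = derived_mask
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
            if self.land_mask.shape != shape[1:]:
                raise FieldValidationError("land_mask shape must be (lat, lon)")
            if np.any(derived_mask & ~self.land_mask):
                raise FieldValidationError("non-finite velocity at a water node")

        # land contributes (0, 0) to every interpolation stencil
        self._u_fill = np.where(self.land_mask[None, :, :], 0.0, np.nan_to_num(self.u))
        self._v_fill = np.where(self.land_mask[None, :, :], 0.0, np.nan_to_num(self.v))

    # -- extent ------------------------------------------------------------

    @property
    def lon_min(self) -> float:
        return float(self.lon_axis[0])

    @property
    def lon_max(self) -> float:
        return float(self.lon_axis[-1])

    @property
    def lat_min(self) -> float:
        return float(self.lat_axis[0])

    @property
    def lat_max(self) -> float:
        return float(self.lat_axis[-1])

    @property
    def t_min(self) -> float:
        return float(self.time_axis[0])

    @property
    def t_max(self) -> float:
        return float(self.time_axis[-1])

    def contains(self, lon, lat):
        """True where (lon, lat) lies inside the grid extent (closed bounds)."""
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def is_land_at(self, lon, lat):
        """Land-mask value of the grid cell containing each point.

        Cells are centred on nodes with half-open edges ([west, east),
        [south, north)), so the containing cell is the nearest node with the
        east/north tie-break used throughout the package.
        """
        ix = np.clip(
            np.floor((np.asarray(lon) - (self.lon_min - 0.5 * self.dx_deg)) / self.dx_deg),
            0,
            self.lon_axis.size - 1,
        ).astype(int)
        iy = np.clip(
            np.floor((np.asarray(lat) - (self.lat_min - 0.5 * self.dy_deg)) / self.dy_deg),
            0,
            self.lat_axis.size - 1,
        ).astype(int)
        return self.land_mask[iy, ix]

    def speed_max(self, day: float) -> float:
        """Largest water-node speed over the snapshots bracketing ``day``."""
        it = int(np.clip(np.floor(day - self.t_min), 0, self.time_axis.size - 2))
        sl = slice(it, it + 2)
        return float(
            np.sqrt(self._u_fill[sl] ** 2 + self._v_fill[sl] ** 2).max()
        )


def velocity_at(field: CurrentField, lon, lat, t: float):
    """Interpolate (u, v) in m s^-1 at positions ``(lon, lat)`` and time ``t``.

    Linear in time between the bracketing daily snapshots, then bilinear in
    lon/lat among the four surrounding nodes; land nodes contribute (0, 0).
    Queries landing exactly on the last grid column/row or the final snapshot
    are treated as inside (closed upper boundary).  ``lon``/``lat`` may be
    scalars or equal-length arrays; ``t`` is a scalar in days.

    Raises
    ------
    OutOfDomainError
        If any query point lies outside the spatial extent or ``t`` outside
        the temporal extent.
    """
    lon_a = np.atleast_1d(np.asarray(lon, dtype=float))
    lat_a = np.atleast_1d(np.asarray(lat, dtype=float))
    scalar = np.isscalar(lon) or (np.asarray(lon).ndim == 0)

    if t < field.t_min or t > field.t_max:
        raise OutOfDomainError(f"time {t} outside [{field.t_min}, {field.t_max}]")
    inside = field.contains(lon_a, lat_a)
    if not np.all(inside):
        i = int(np.argmin(inside))
        raise OutOfDomainError(
            f"position (lon={lon_a[i]}, lat={lat_a[i]}) outside grid extent"
        )

    nt = field.time_axis.size
    it = int(np.clip(np.floor(t - field.t_min), 0, nt - 2))
    wt = (t - field.t_min) - it
    uu = (1.0 - wt) * field._u_fill[it] + wt * field._u_fill[it + 1]
    vv = (1.0 - wt) * field._v_fill[it] + wt * field._v_fill[it + 1]

    nx = field.lon_axis.size
    ny = field.lat_axis.size
    fx = (lon_a - field.lon_min) / field.dx_deg
    fy = (lat_a - field.lat_min) / field.dy_deg
    ix = np.clip(np.floor(fx), 0, nx - 2).astype(int)
    iy = np.clip(np.floor(fy), 0, ny - 2).astype(int)
    tx = fx - ix
    ty = fy - iy

    def bilin(a):
        return (
            a[iy, ix] * (1.0 - tx) * (1.0 - ty)
            + a[iy, ix + 1] * tx * (1.0 - ty)
            + a[iy + 1, ix] * (1.0 - tx) * ty
            + a[iy + 1, ix + 1] * tx * ty
        )

    u_out = bilin(uu)
    v_out = bilin(vv)
    if scalar:
        return float(u_out[0]), float(v_out[0])
    return u_out, v_out


def grid_spacing_meters(field: CurrentField, lat: float) -> float:
    """Zonal node spacing in metres at latitude ``lat``.

    ``dx_deg * 111,320 * cos(lat)``; zero at the poles (callers must guard).
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    return field.dx_deg * METERS_PER_DEGREE * np.cos(np.radians(lat))


def meridional_spacing_meters(field: CurrentField) -> float:
    """Meridional node spacing in metres (latitude-independent)."""
    return field.dy_deg * METERS_PER_DEGREE


def min_node_spacing_meters(field: CurrentField) -> float:
    """Smallest node spacing over the grid's latitude range.

    The minimum of the meridional spacing and the zonal spacing at the
    highest absolute latitude of the grid; used by the time-step rule that
    keeps the per-substep displacement below one cell.
    """
    lat_extreme = max(abs(field.lat_min), abs(field.lat_max))
    return min(grid_spacing_meters(field, lat_extreme), meridional_spacing_meters(field))


def load_current_field(path, names: dict | None = None) -> CurrentField:
    """Read a netCDF forcing file into a validated :class:`CurrentField`.

    ``names`` maps the logical axis/variable roles (lon, lat, time, u, v) to
    the names used in the file; defaults follow HYCOM conventions
    (``water_u``/``water_v``).  Missing-valued velocity nodes become
    ``land_mask=True``.
    """
    nm = dict(DEFAULT_VARIABLE_NAMES)
    if names:
        nm.update(names)
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        for role in ("lon", "lat", "time", "u", "v"):
            if nm[role] not in ds.variables:
                raise FieldFormatError(
                    f"variable '{nm[role]}' (role: {role}) not found in {path}"
                )
        return CurrentField(
            lon_axis=ds[nm["lon"]].values,
            lat_axis=ds[nm["lat"]].values,
            time_axis=ds[nm["time"]].values,
            u=ds[nm["u"]].values,
            v=ds[nm["v"]].values,
        )


def write_current_field(field: CurrentField, path, names: dict | None = None) -> None:
    """Write a :class:`CurrentField` to netCDF (land nodes as NaN)."""
    nm = dict(DEFAULT_VARIABLE_NAMES)
    if names:
        nm.update(names)
    u = np.where(field.land_mask[None, :, :], np.nan, field.u)
    v = np.where(field.land_mask[None, :, :], np.nan, field.v)
    ds = xr.Dataset(
        {
            nm["u"]: ((nm["time"], nm["lat"], nm["lon"]), u, {"units": "m s-1"}),
            nm["v"]: ((nm["time"], nm["lat"], nm["lon"]), v, {"units": "m s-1"}),
        },
        coords={
            nm["lon"]: (nm["lon"], field.lon_axis, {"units": "degrees_east"}),
            nm["lat"]: (nm["lat"], field.lat_axis, {"units": "degrees_north"}),
            nm["time"]: (nm["time"], field.time_axis, {"units": "days since simulation origin"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")
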