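"""Gridded u/v wind fields and trilinear interpolation to fix positions/times.

A :class:`WindGrid` holds eastward (u) and northward (v) wind components on a
regular (time, lat, lon) grid — typically 6-hourly, 2.5 degree reanalysis
output at a single pressure level.  :func:`interpolate_wind` interpolates the
*components* trilinearly and derives speed and direction from the
interpolated components (never the other way around, which would bias speed
near direction changes).

Direction convention: ``dir_to`` is the bearing the wind blows TOWARD
(vector heading of (u, v)), so a wind with ``dir_to`` equal to the travel
bearing is a pure tailwind.

Queries outside the grid's bounding box or time span raise
:class:`OutOfDomainError`; no extrapolation is performed.  Longitudes are not
wrapped across the antimeridian (an African-domain grid never crosses it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .geodesy import normalize_bearing

__all__ = ["WindGrid", "WindSample", "OutOfDomainError", "wind_to_sample", "interpolate_wind"]


class OutOfDomainError(ValueError):
    """Query point outside the wind grid's spatial or temporal extent."""


@dataclass(frozen=True)
class WindSample:
    """Wind at a single point: components in m/s, derived speed and heading."""

    u: float
    v: float

    @property
    def speed(self) -> float:
        """Total wind speed W = sqrt(u^2 + v^2), m/s."""
        return float(np.hypot(self.u, self.v))

    @property
    def dir_to(self) -> float:
        """Bearing the wind blows toward, degrees in [0, 360)."""
        return normalize_bearing(np.degrees(np.arctan2(self.u, self.v)))


def wind_to_sample(u: float, v: float) -> WindSample:
    """Wrap raw components into a :class:`WindSample`."""
    if not (np.isfinite(u) and np.isfinite(v)):
        raise ValueError("wind components must be finite")
    return WindSample(float(u), float(v))


def _check_regular(axis: np.ndarray, name: str) -> None:
    if axis.ndim != 1 or len(axis) < 2:
        raise ValueError(f"{name} axis must be 1-D with >= 2 values")
    d = np.diff(axis.astype(float))
    if not (d > 0).all():
        raise ValueError(f"{name} axis must be strictly ascending")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{name} axis must be regularly spaced")


@dataclass
class WindGrid:
    """Regular (time, lat, lon) grid of u/v wind components in m/s."""

    lons: np.ndarray
    lats: np.ndarray
    times: np.ndarray  # datetime64[ns], ascending, regular
    u: np.ndarray  # (time, lat, lon)
    v: np.ndarray
    _interp_u: Optional[RegularGridInterpolator] = field(default=None, repr=False, compare=False)
    _interp_v: Optional[RegularGridInterpolator] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        _check_regular(self.lons, "lon")
        _check_regular(self.lats, "lat")
        _check_regular(self.times.astype("int64"), "time")
        shape = (len(self.times), len(self.lats), len(self.lons))
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v must have shape {shape}")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("u/v must be finite")

    # -- time coordinate as float seconds since the first snapshot ----------
    def _tsec(self, t) -> np.ndarray:
        t = np.asarray(t, dtype="datetime64[ns]")
        return (t - self.times[0]) / np.timedelta64(1, "s")

    def _interpolators(self):
        if self._interp_u is None:
            axes = (self._tsec(self.times), self.lats, self.lons)
            self._interp_u = RegularGridInterpolator(axes, self.u, bounds_error=True)
            self._interp_v = RegularGridInterpolator(axes, self.v, bounds_error=True)
        return self._interp_u, self._interp_v

    def interp_uv(self, lon, lat, t, *, strict: bool = True):
        """Trilinearly interpolated (u, v) arrays at query points.

        With ``strict`` (default) an out-of-domain query raises
        :class:`OutOfDomainError`; otherwise such queries yield NaN.
        """
        iu, iv = self._interpolators()
        pts = np.column_stack(
            [
                np.atleast_1d(self._tsec(t)),
                np.atleast_1d(np.asarray(lat, dtype=float)),
                np.atleast_1d(np.asarray(lon, dtype=float)),
            ]
        )
        if strict:
            try:
                return iu(pts), iv(pts)
            except ValueError as exc:
                raise OutOfDomainError(str(exc)) from exc
        inside = np.ones(len(pts), dtype=bool)
        for j, axis in enumerate((self._tsec(self.times), self.lats, self.lons)):
            inside &= (pts[:, j] >= axis[0]) & (pts[:, j] <= axis[-1])
        u = np.full(len(pts), np.nan)
        v = np.full(len(pts), np.nan)
        if inside.any():
            u[inside] = iu(pts[inside])
            v[inside] = iv(pts[inside])
        return u, v

    # -- I/O -----------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"u": (("time", "lat", "lon"), self.u), "v": (("time", "lat", "lon"), self.v)},
            coords={"time": self.times, "lat": self.lats, "lon": self.lons},
            attrs={"units": "m s-1", "convention": "u eastward, v northward"},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "WindGrid":
        ds = ds.sortby(["time", "lat", "lon"])
        return cls(
            lons=ds["lon"].values,
            lats=ds["lat"].values,
            times=ds["time"].values,
            u=ds["u"].transpose("time", "lat", "lon").values,
            v=ds["v"].transpose("time", "lat", "lon").values,
        )

    @classmethod
    def from_netcdf(cls, path) -> "WindGrid":
        try:
            ds = xr.open_dataset(path)
        except (ValueError, OSError):
            ds = xr.open_dataset(path, engine="scipy")
        with ds:
            return cls.from_dataset(ds.load())

    def to_csv(self, path) -> None:
        """Long-format CSV fallback: time, lat, lon, u, v."""
        df = self.to_dataset().to_dataframe().reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WindGrid":
        df = pd.read_csv(path, parse_dates=["time"])
        ds = df.set_index(["time", "lat", "lon"]).to_xarray()
        return cls.from_dataset(ds)


def interpolate_wind(grid: WindGrid, lon: float, lat: float, t) -> WindSample:
    """Wind at a single position and UTC time, trilinearly interpolated."""
    u, v = grid.interp_uv(lon, lat, t, strict=True)
    return WindSample(float(u[0]), float(v[0]))
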