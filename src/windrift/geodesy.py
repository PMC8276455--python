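"""Spherical-earth great-circle primitives.

All routines assume a spherical earth of radius :data:`R_EARTH_KM` (the IUGG
mean radius, 6371.0088 km).  At flyway scale (thousands of km) the spherical
approximation is accurate to a few km, far below GPS-track noise.

Conventions
-----------
* longitude: degrees east, normalized to ``[-180, 180)``
* latitude:  degrees north, must lie in ``[-90, 90]``
* bearing:   degrees clockwise from geographic north, normalized to
  ``[0, 360)``; a signed view in ``(-180, 180]`` is available through
  :func:`signed_bearing` for westward-sector filters.

Scalar functions operate on :class:`GeoPoint`; the ``*_deg`` variants are
vectorized over numpy arrays of plain lon/lat degrees and are what the
table-oriented modules use internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "R_EARTH_KM",
    "GeoPoint",
    "normalize_lon",
    "normalize_bearing",
    "signed_bearing",
    "gc_distance",
    "gc_distance_deg",
    "initial_bearing",
    "initial_bearing_deg",
    "destination",
    "destination_deg",
    "densify_ring",
    "nearest_point_on_boundary",
    "ring_from_geojson",
]

#: IUGG mean earth radius in kilometres.
R_EARTH_KM = 6371.0088


class CoincidentPointsError(ValueError):
    """Raised when a direction is requested between coincident points."""


def normalize_lon(lon: float) -> float:
    """Normalize a longitude to ``[-180, 180)``."""
    return float((lon + 180.0) % 360.0 - 180.0)


def normalize_bearing(deg) -> float | np.ndarray:
    """Normalize a bearing (degrees) to ``[0, 360)``. Idempotent."""
    out = np.asarray(deg, dtype=float) % 360.0
    # -0.0 % 360 gives -0.0 on some platforms; force +0.0
    out = np.where(out == 360.0, 0.0, out) + 0.0
    if np.isscalar(deg) or np.ndim(deg) == 0:
        return float(out)
    return out


def signed_bearing(deg) -> float | np.ndarray:
    """Signed view of a bearing in ``(-180, 180]`` (negative = westward)."""
    b = normalize_bearing(deg)
    out = np.where(np.asarray(b) > 180.0, np.asarray(b) - 360.0, b)
    if np.isscalar(deg) or np.ndim(deg) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GeoPoint:
    """A position on the sphere; ``lon`` is normalized on construction."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", normalize_lon(self.lon))
        object.__setattr__(self, "lat", float(self.lat))


# ---------------------------------------------------------------------------
# vectorized core


def gc_distance_deg(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle (haversine) distance in km between lon/lat degree arrays.

    The haversine form is numerically stable for small separations, which
    dominate hourly GPS steps.
    """
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * R_EARTH_KM * np.arcsin(np.sqrt(a))


def initial_bearing_deg(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial bearing (degrees in [0, 360)) of the great circle 1 -> 2.

    Coincident points yield NaN; the scalar wrapper raises instead.
    """
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    brg = normalize_bearing(np.degrees(np.arctan2(y, x)))
    coincident = (np.asarray(lon1) == np.asarray(lon2)) & (np.asarray(lat1) == np.asarray(lat2))
    return np.where(coincident, np.nan, brg)


def destination_deg(lon, lat, bearing, d_km):
    """Destination lon/lat (degrees) after travelling ``d_km`` along ``bearing``."""
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lam1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing, dtype=float))
    delta = np.asarray(d_km, dtype=float) / R_EARTH_KM
    sinphi2 = np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    sinphi2 = np.clip(sinphi2, -1.0, 1.0)
    phi2 = np.arcsin(sinphi2)
    y = np.sin(theta) * np.sin(delta) * np.cos(phi1)
    x = np.cos(delta) - np.sin(phi1) * sinphi2
    lam2 = lam1 + np.arctan2(y, x)
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    return lon2, np.degrees(phi2)


# ---------------------------------------------------------------------------
# scalar GeoPoint API


def gc_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points in km (symmetric, <= pi*R)."""
    return float(gc_distance_deg(a.lon, a.lat, b.lon, b.lat))


def initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Initial bearing of the great circle from *a* to *b*, in ``[0, 360)``.

    Raises
    ------
    CoincidentPointsError
        If ``a == b`` (the direction is undefined).
    """
    if a.lon == b.lon and a.lat == b.lat:
        raise CoincidentPointsError(f"bearing undefined for coincident points {a}")
    return float(initial_bearing_deg(a.lon, a.lat, b.lon, b.lat))


def destination(a: GeoPoint, bearing: float, d_km: float) -> GeoPoint:
    """Point reached from *a* travelling ``d_km`` along the great circle
    whose initial bearing at *a* is ``bearing``."""
    if d_km < 0:
        raise ValueError("distance must be non-negative")
    lon2, lat2 = destination_deg(a.lon, a.lat, bearing, d_km)
    return GeoPoint(float(lon2), float(lat2))


# ---------------------------------------------------------------------------
# boundary handling


def _slerp(p1: GeoPoint, p2: GeoPoint, n_intermediate: int) -> list[GeoPoint]:
    """Evenly spaced intermediate points on the great-circle arc p1 -> p2."""
    v1 = _unit(p1)
    v2 = _unit(p2)
    omega = math.acos(max(-1.0, min(1.0, float(np.dot(v1, v2)))))
    if omega == 0.0 or n_intermediate <= 0:
        return []
    out = []
    for i in range(1, n_intermediate + 1):
        f = i / (n_intermediate + 1)
        v = (math.sin((1 - f) * omega) * v1 + math.sin(f * omega) * v2) / math.sin(omega)
        lat = math.degrees(math.asin(max(-1.0, min(1.0, v[2]))))
        lon = math.degrees(math.atan2(v[1], v[0]))
        out.append(GeoPoint(lon, lat))
    return out


def _unit(p: GeoPoint) -> np.ndarray:
    phi = math.radians(p.lat)
    lam = math.radians(p.lon)
    return np.array([math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)])


def densify_ring(boundary: Sequence[GeoPoint], max_spacing_km: float = 10.0) -> list[GeoPoint]:
    """Insert great-circle intermediate vertices so that no edge of the ring
    exceeds ``max_spacing_km``.  The ring is treated as closed (last vertex
    connects back to the first) when its endpoints differ."""
    if len(boundary) < 2:
        raise ValueError("boundary needs at least 2 vertices")
    pts = list(boundary)
    if pts[0] != pts[-1]:
        pts = pts + [pts[0]]
    out: list[GeoPoint] = []
    for p1, p2 in zip(pts[:-1], pts[1:]):
        out.append(p1)
        d = gc_distance(p1, p2)
        if d > max_spacing_km:
            n = int(math.ceil(d / max_spacing_km)) - 1
            out.extend(_slerp(p1, p2, n))
    return out


def nearest_point_on_boundary(
    p: GeoPoint, boundary: Sequence[GeoPoint], max_spacing_km: float = 10.0
) -> GeoPoint:
    """Vertex of the densified boundary closest to *p*.

    Edges are densified to <= ``max_spacing_km`` vertex spacing before the
    arg-min scan, which bounds the error of the vertex approximation by the
    spacing itself.
    """
    dense = densify_ring(boundary, max_spacing_km)
    lons = np.array([q.lon for q in dense])
    lats = np.array([q.lat for q in dense])
    d = gc_distance_deg(p.lon, p.lat, lons, lats)
    i = int(np.argmin(d))
    return dense[i]


def ring_from_geojson(source) -> list[GeoPoint]:
    """Exterior ring of the first Polygon in a GeoJSON file, path or mapping.

    Accepts a Feature, FeatureCollection, Polygon or MultiPolygon; MultiPolygon
    yields the first polygon's exterior ring.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
    else:
        obj = source
    geom = obj
    if obj.get("type") == "FeatureCollection":
        geom = obj["features"][0]["geometry"]
    elif obj.get("type") == "Feature":
        geom = obj["geometry"]
    if geom["type"] == "Polygon":
        ring = geom["coordinates"][0]
    elif geom["type"] == "MultiPolygon":
        ring = geom["coordinates"][0][0]
    else:
        raise ValueError(f"unsupported GeoJSON geometry {geom['type']!r}")
    return [GeoPoint(float(lon), float(lat)) for lon, lat in ring]
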