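"""Tailwind/sidewind decomposition, the Local Wind Gain Index (LWGI) and
drift/compensation classification.

The core quantity is the LWGI,

    LWGI = (W cos(theta) - W cos(beta)) / W = cos(theta) - cos(beta),

where W is total wind speed, theta the angle between the wind heading and the
bird's realized travel direction, and beta the angle between the wind heading
and the great-circle direction (GCR) to the seasonal goal.  LWGI = 0 means
the bird gains nothing by deviating from the GCR (theta = beta); LWGI = 1
means it gained the equivalent of the full wind speed (e.g. theta = 0,
beta = 90 deg); the maximum LWGI = 2 occurs for a pure tailwind along the
chosen direction that would be a pure headwind along the GCR.  LWGI is
undefined at W = 0 (the formula divides by W) and NaN is returned.

Orientation responses to sidewinds are classified from the ratio of the
sideward ground-displacement rate to the sidewind strength relative to the
GCR: overcompensation (ratio < -0.2), full compensation (-0.2, 0.2), partial
compensation (0.2, 0.8), full drift (0.8, 1.2), overdrift (> 1.2); segments
with |sidewind| < 0.5 m/s are left unclassified ('no_sidewind').  Boundary
ratios fall to the lower-ratio category.

Sign convention: positive sidewind and positive sideward rate both mean
"toward the right of the reference bearing", so drifting with the wind gives
a positive ratio on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geodesy
from .geodesy import GeoPoint
from .wind_field import WindGrid, WindSample

__all__ = [
    "ALEGRANZA",
    "MADAGASCAR_COAST_APPROX",
    "GoalSpec",
    "goal_bearing",
    "decompose",
    "angle_between",
    "lwgi",
    "sideward_rate",
    "classify_orientation",
    "classify_orientation_many",
    "annotate_travel_days",
    "ORIENTATION_CATEGORIES",
]

KMH_TO_MS = 1000.0 / 3600.0

#: Centre of Alegranza islet (29 deg 24' N, 13 deg 30' W), the spring goal.
ALEGRANZA = GeoPoint(lon=-13.5, lat=29.4)

#: Coarse synthetic outline of the Madagascar coastline (~16 vertices,
#: lon/lat degrees).  Adequate as an autumn goal boundary for simulation and
#: testing; substitute a real coastline GeoJSON for production use.
MADAGASCAR_COAST_APPROX: tuple[GeoPoint, ...] = tuple(
    GeoPoint(lon, lat)
    for lon, lat in [
        (49.35, -12.10),
        (50.20, -14.80),
        (50.48, -15.70),
        (49.90, -17.10),
        (49.50, -18.50),
        (48.60, -21.20),
        (47.60, -24.80),
        (45.20, -25.60),
        (44.00, -24.00),
        (43.25, -22.20),
        (43.90, -17.50),
        (44.40, -16.20),
        (46.30, -15.00),
        (47.50, -14.60),
        (48.00, -13.20),
    ]
)

ORIENTATION_CATEGORIES = (
    "overcompensation",
    "full_compensation",
    "partial_compensation",
    "full_drift",
    "overdrift",
    "no_sidewind",
)

#: Ratio thresholds separating the five orientation categories.
RATIO_THRESHOLDS = (-0.2, 0.2, 0.8, 1.2)

#: Below this sidewind strength (m/s) the ratio is not classified.
MIN_SIDEWIND_MS = 0.5


@dataclass(frozen=True)
class GoalSpec:
    """Seasonal goal: a point (spring: the colony) or a boundary whose nearest
    point is the goal (autumn: the Madagascar coastline)."""

    season: str
    point: Optional[GeoPoint] = None
    boundary: Optional[Sequence[GeoPoint]] = None
    densify_km: float = 10.0
    _dense: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.season not in ("autumn", "spring"):
            raise ValueError("season must be 'autumn' or 'spring'")
        if self.season == "spring" and self.point is None:
            raise ValueError("spring goal requires a point")
        if self.season == "autumn" and self.boundary is None:
            raise ValueError("autumn goal requires a boundary polygon")

    def densified(self) -> tuple:
        if self._dense is None:
            dense = tuple(geodesy.densify_ring(self.boundary, self.densify_km))
            object.__setattr__(self, "_dense", dense)
        return self._dense

    @classmethod
    def default(cls, season: str) -> "GoalSpec":
        """Built-in study goals: Madagascar outline (autumn), Alegranza (spring)."""
        if season == "autumn":
            return cls(season="autumn", boundary=MADAGASCAR_COAST_APPROX)
        return cls(season="spring", point=ALEGRANZA)


def goal_bearing(p: GeoPoint, season: str, goal_spec: GoalSpec) -> float:
    """Initial bearing of the GCR from *p* to the seasonal goal.

    Autumn: bearing to the nearest (densified) vertex of the goal boundary.
    Spring: bearing to the goal point.  Raises if *p* coincides with the goal.
    """
    if season == "spring":
        target = goal_spec.point
    else:
        dense = goal_spec.densified()
        lons = np.array([q.lon for q in dense])
        lats = np.array([q.lat for q in dense])
        d = geodesy.gc_distance_deg(p.lon, p.lat, lons, lats)
        target = dense[int(np.argmin(d))]
    return geodesy.initial_bearing(p, target)


def goal_bearing_many(lons, lats, season: str, goal_spec: GoalSpec) -> np.ndarray:
    """Vectorized :func:`goal_bearing` over arrays of positions."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if season == "spring":
        return geodesy.initial_bearing_deg(lons, lats, goal_spec.point.lon, goal_spec.point.lat)
    dense = goal_spec.densified()
    blons = np.array([q.lon for q in dense])
    blats = np.array([q.lat for q in dense])
    # pairwise distances fix x boundary-vertex; argmin per fix
    d = geodesy.gc_distance_deg(
        lons[:, None], lats[:, None], blons[None, :], blats[None, :]
    )
    idx = np.argmin(d, axis=1)
    return geodesy.initial_bearing_deg(lons, lats, blons[idx], blats[idx])


def angle_between(a, b) -> np.ndarray | float:
    """Unsigned angle between two bearings, folded into [0, 180] degrees."""
    d = np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0)
    out = np.where(d > 180.0, 360.0 - d, d)
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return float(out)
    return out


def decompose(wind, ref_bearing):
    """Tailwind and sidewind components (m/s) of *wind* relative to a bearing.

    ``tail = W cos(dir_to - ref)`` (positive = following wind) and
    ``side = W sin(dir_to - ref)`` (positive = pushing to the RIGHT of the
    reference bearing).  Accepts a :class:`WindSample` or (W, dir_to) arrays.
    """
    if isinstance(wind, WindSample):
        W, dir_to = wind.speed, wind.dir_to
    else:
        W, dir_to = wind
    delta = np.radians(np.asarray(dir_to, dtype=float) - np.asarray(ref_bearing, dtype=float))
    W = np.asarray(W, dtype=float)
    tail = W * np.cos(delta)
    side = W * np.sin(delta)
    if np.ndim(tail) == 0:
        return float(tail), float(side)
    return tail, side


def lwgi(W, theta, beta):
    """Local Wind Gain Index, cos(theta) - cos(beta); NaN where W == 0.

    ``theta`` and ``beta`` are angles in degrees between the wind heading and
    the realized travel direction / the GCR direction respectively (cos is
    even and periodic, so no prior folding is required).
    """
    W = np.asarray(W, dtype=float)
    val = np.cos(np.radians(np.asarray(theta, dtype=float))) - np.cos(
        np.radians(np.asarray(beta, dtype=float))
    )
    out = np.where(W > 0, val, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def sideward_rate(speed_kmh, bearing, goal_bearing_deg):
    """Sideward ground-displacement rate in m/s relative to the GCR bearing.

    Positive = to the right of the goal bearing.
    """
    v = np.asarray(speed_kmh, dtype=float) * KMH_TO_MS
    out = v * np.sin(
        np.radians(np.asarray(bearing, dtype=float) - np.asarray(goal_bearing_deg, dtype=float))
    )
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class OrientationOutcome:
    ratio: float  # NaN for no_sidewind
    category: str


def _classify_ratio(ratio: np.ndarray) -> np.ndarray:
    t1, t2, t3, t4 = RATIO_THRESHOLDS
    # boundary values fall to the lower-ratio category
    cats = np.full(ratio.shape, "overdrift", dtype=object)
    cats[ratio <= t4] = "full_drift"
    cats[ratio <= t3] = "partial_compensation"
    cats[ratio <= t2] = "full_compensation"
    cats[ratio <= t1] = "overcompensation"
    return cats


def classify_orientation_many(side_rate, sidewind_gcr, min_sidewind: float = MIN_SIDEWIND_MS):
    """Vectorized classification; returns (ratio, category) arrays.

    Ratio is NaN where |sidewind| < ``min_sidewind`` (category 'no_sidewind').
    """
    sr = np.atleast_1d(np.asarray(side_rate, dtype=float))
    sw = np.atleast_1d(np.asarray(sidewind_gcr, dtype=float))
    weak = np.abs(sw) < min_sidewind
    ratio = np.full(sw.shape, np.nan)
    np.divide(sr, sw, out=ratio, where=~weak)
    cats = _classify_ratio(ratio)
    cats[weak] = "no_sidewind"
    return ratio, cats


def classify_orientation(
    side_rate: float, sidewind_gcr: float, min_sidewind: float = MIN_SIDEWIND_MS
) -> OrientationOutcome:
    """Classify one segment's orientation response to sidewind."""
    ratio, cats = classify_orientation_many([side_rate], [sidewind_gcr], min_sidewind)
    return OrientationOutcome(float(ratio[0]), str(cats[0]))


def annotate_travel_days(
    segments: pd.DataFrame,
    grid: WindGrid,
    season: str,
    goal_spec: Optional[GoalSpec] = None,
    sample_at: str = "start",
):
    """Wind-annotate segments and aggregate daily wind means over travel days.

    Wind is sampled at each segment's start fix (position and time) by
    default; ``sample_at='mid'`` samples the temporal/spatial midpoint
    instead.  For each segment the function computes the decomposition
    relative to the realized bearing and to the GCR bearing at the start fix,
    the LWGI, the sideward displacement rate, and the orientation category.
    Segments outside the wind grid are flagged (NaN wind) and excluded from
    daily means.

    Returns
    -------
    (annotated, daily, n_excluded)
        ``annotated``: the segment table with wind columns appended;
        ``daily``: per bird-day means over travel segments;
        ``n_excluded``: count of segments outside the wind grid.
    """
    if goal_spec is None:
        goal_spec = GoalSpec.default(season)
    seg = segments.reset_index(drop=True).copy()
    if sample_at == "start":
        q_lon = seg["lon1"].to_numpy(float)
        q_lat = seg["lat1"].to_numpy(float)
        q_t = seg["t_start"].to_numpy()
    elif sample_at == "mid":
        from .track_pipeline import _segment_midpoints

        t_mid, q_lon, q_lat = _segment_midpoints(seg)
        q_t = t_mid.to_numpy()
    else:
        raise ValueError("sample_at must be 'start' or 'mid'")

    u, v = grid.interp_uv(q_lon, q_lat, q_t, strict=False)
    n_excluded = int(np.isnan(u).sum())
    W = np.hypot(u, v)
    dir_to = geodesy.normalize_bearing(np.degrees(np.arctan2(u, v)))

    gcr = goal_bearing_many(seg["lon1"], seg["lat1"], season, goal_spec)
    theta = angle_between(dir_to, seg["bearing"].to_numpy(float))
    beta = angle_between(dir_to, gcr)
    tail_track, side_track = decompose((W, dir_to), seg["bearing"].to_numpy(float))
    tail_gcr, side_gcr = decompose((W, dir_to), gcr)
    srate = sideward_rate(seg["speed_kmh"].to_numpy(float), seg["bearing"].to_numpy(float), gcr)
    ratio, cats = classify_orientation_many(srate, side_gcr)
    cats = cats.astype(object)
    cats[np.isnan(u)] = None

    seg["u"] = u
    seg["v"] = v
    seg["W"] = W
    seg["gcr_bearing"] = gcr
    seg["theta"] = theta
    seg["beta"] = beta
    seg["tailwind_track"] = tail_track
    seg["sidewind_track"] = side_track
    seg["tailwind_gcr"] = tail_gcr
    seg["sidewind_gcr"] = side_gcr
    seg["lwgi"] = lwgi(W, theta, beta)
    seg["side_rate"] = srate
    seg["ratio"] = ratio
    seg["orientation_category"] = cats

    trav = seg.loc[seg["is_travel"] & np.isfinite(seg["u"])].copy()
    trav["date"] = pd.to_datetime(trav["t_start"]).dt.normalize()
    daily = (
        trav.groupby(["bird_id", "date"])[
            ["tailwind_track", "sidewind_track", "tailwind_gcr", "sidewind_gcr", "lwgi"]
        ]
        .mean()  # NaN LWGI (W == 0) excluded by nan-aware mean
        .reset_index()
    )
    return seg, daily, n_excluded
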