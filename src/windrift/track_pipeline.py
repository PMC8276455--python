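"""Hourly resampling, movement statistics and travel/stop-over segmentation.

The pipeline consumes a tidy fix table (one GPS record per row) and produces

1. an hourly-resampled fix table (:func:`resample_hourly`),
2. per-step movement statistics (:func:`compute_segments`),
3. per bird-day summaries with a travel/stop-over classification
   (:func:`summarize_days`), and
4. stop-over events as maximal runs of consecutive stop-over days
   (:func:`segment_stopovers`).

Defaults follow standard practice for hourly biologging data: resampling
tolerance of 10 min around each whole hour, a 5 km/h hourly speed threshold
separating directed travel from localized foraging/resting, and a 100 km
daily-beeline threshold separating travel days from stop-over days.

All timestamps are UTC (naive); there is no local-time conversion — the
diurnal/nocturnal split uses geometric solar elevation, which already encodes
local day/night.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geodesy

__all__ = [
    "read_tracks",
    "resample_hourly",
    "compute_segments",
    "solar_elevation",
    "summarize_days",
    "segment_stopovers",
]

FIX_COLUMNS = ["bird_id", "t", "lon", "lat"]


def read_tracks(path) -> pd.DataFrame:
    """Read a track CSV (columns bird_id, timestamp, lon, lat[, altitude_m]).

    Timestamps are parsed as UTC and the table is sorted by (bird_id, t).
    """
    df = pd.read_csv(path)
    tcol = "timestamp" if "timestamp" in df.columns else "t"
    df["t"] = pd.to_datetime(df[tcol], utc=True).dt.tz_localize(None)
    if tcol != "t":
        df = df.drop(columns=[tcol])
    keep = FIX_COLUMNS + (["altitude_m"] if "altitude_m" in df.columns else [])
    return df[keep].sort_values(["bird_id", "t"]).reset_index(drop=True)


def _require_sorted(fixes: pd.DataFrame) -> None:
    for bird, g in fixes.groupby("bird_id", sort=False):
        if not g["t"].is_monotonic_increasing:
            raise ValueError(f"fixes for bird {bird!r} are not time-sorted")
        if g["t"].duplicated().any():
            raise ValueError(f"duplicate timestamps for bird {bird!r}")


def resample_hourly(fixes: pd.DataFrame, tol_min: float = 10.0) -> pd.DataFrame:
    """Reduce a fix table to at most one fix per whole-hour mark per bird.

    For every whole hour with at least one fix within ``±tol_min`` minutes,
    the candidate nearest in time is kept (the earlier fix wins exact ties).
    Each source fix can serve at most one hour mark.  Fixes farther than
    ``tol_min`` from any whole hour are dropped.
    """
    _require_sorted(fixes)
    if fixes.empty:
        return fixes.copy()
    mark = fixes["t"].dt.round("h")
    offset = (fixes["t"] - mark).abs()
    ok = fixes.loc[offset <= pd.Timedelta(minutes=tol_min)].copy()
    ok["_mark"] = mark.loc[ok.index]
    ok["_off"] = offset.loc[ok.index]
    ok = ok.sort_values(["bird_id", "_mark", "_off", "t"], kind="stable")
    out = ok.drop_duplicates(subset=["bird_id", "_mark"], keep="first")
    return (
        out.drop(columns=["_mark", "_off"])
        .sort_values(["bird_id", "t"])
        .reset_index(drop=True)
    )


def compute_segments(
    fixes: pd.DataFrame,
    travel_kmh: float = 5.0,
    max_gap_h: float = 1.2,
) -> pd.DataFrame:
    """Movement statistics from each resampled fix to the next.

    One segment per consecutive same-bird fix pair with a positive duration
    of at most ``max_gap_h`` hours (longer gaps break the hourly track and
    are not summed into travel time).  ``is_travel`` applies the hourly speed
    threshold ``speed_kmh > travel_kmh``.
    """
    _require_sorted(fixes)
    if len(fixes) < 2:
        raise ValueError("need at least 2 fixes to form segments")
    df = fixes.reset_index(drop=True)
    nxt = df.groupby("bird_id", sort=False).shift(-1)
    valid = nxt["t"].notna()
    seg = pd.DataFrame(
        {
            "bird_id": df.loc[valid, "bird_id"].to_numpy(),
            "t_start": df.loc[valid, "t"].to_numpy(),
            "t_end": nxt.loc[valid, "t"].to_numpy(),
            "lon1": df.loc[valid, "lon"].to_numpy(float),
            "lat1": df.loc[valid, "lat"].to_numpy(float),
            "lon2": nxt.loc[valid, "lon"].to_numpy(float),
            "lat2": nxt.loc[valid, "lat"].to_numpy(float),
        }
    )
    seg["duration_h"] = (seg["t_end"] - seg["t_start"]) / pd.Timedelta(hours=1)
    if (seg["duration_h"] <= 0).any():
        raise ValueError("non-increasing timestamps within a bird's track")
    seg = seg.loc[seg["duration_h"] <= max_gap_h].reset_index(drop=True)
    seg["step_km"] = geodesy.gc_distance_deg(seg["lon1"], seg["lat1"], seg["lon2"], seg["lat2"])
    seg["speed_kmh"] = seg["step_km"] / seg["duration_h"]
    seg["bearing"] = geodesy.initial_bearing_deg(seg["lon1"], seg["lat1"], seg["lon2"], seg["lat2"])
    seg["is_travel"] = seg["speed_kmh"] > travel_kmh
    return seg


def solar_elevation(lon, lat, t) -> np.ndarray:
    """Geometric solar elevation angle (degrees) at lon/lat and UTC time(s).

    Uses the standard low-precision solar-position expansion (fractional-year
    Fourier series for declination and the equation of time); accurate to a
    fraction of a degree, ample for a day/night split at 0 degrees elevation.
    """
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(t, dtype="datetime64[ns]")))
    lon = np.broadcast_to(np.asarray(lon, dtype=float), t.shape)
    lat = np.broadcast_to(np.asarray(lat, dtype=float), t.shape)
    doy = t.dayofyear.to_numpy()
    hours = t.hour + t.minute / 60.0 + t.second / 3600.0
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    tst = hours * 60.0 + eqtime + 4.0 * lon  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle
    phi = np.radians(lat)
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def _segment_midpoints(seg: pd.DataFrame):
    """Temporal and spatial midpoints of segments (spatial: half-step along
    the initial bearing; start point for zero-length steps)."""
    t_mid = seg["t_start"] + (seg["t_end"] - seg["t_start"]) / 2
    moving = seg["step_km"].to_numpy() > 0
    lon_m = seg["lon1"].to_numpy(float).copy()
    lat_m = seg["lat1"].to_numpy(float).copy()
    if moving.any():
        lon2, lat2 = geodesy.destination_deg(
            seg.loc[moving, "lon1"],
            seg.loc[moving, "lat1"],
            seg.loc[moving, "bearing"],
            seg.loc[moving, "step_km"] / 2.0,
        )
        lon_m[moving] = lon2
        lat_m[moving] = lat2
    return t_mid, lon_m, lat_m


def summarize_days(
    segments: pd.DataFrame,
    fixes: pd.DataFrame,
    stopover_km: float = 100.0,
    night_elevation_deg: float = 0.0,
) -> pd.DataFrame:
    """Per bird-day aggregates and travel/stop-over classification.

    Beeline is the great-circle distance from the first to the last fix of the
    UTC calendar day.  Travel hours sum the durations of travel segments
    assigned to the day of their start fix; the diurnal/nocturnal split uses
    geometric solar elevation (> ``night_elevation_deg`` = diurnal) evaluated
    at the segment's temporal and spatial midpoint.  Days with fewer than two
    fixes have an undefined beeline and are flagged (``day_class='flagged'``)
    rather than counted as stop-over.

    Returns one row per bird-day with ``day_class`` in
    {'travel', 'stopover', 'flagged'}.
    """
    fx = fixes.copy()
    fx["date"] = fx["t"].dt.normalize()
    first = fx.groupby(["bird_id", "date"], sort=True).first()
    last = fx.groupby(["bird_id", "date"], sort=True).last()
    n = fx.groupby(["bird_id", "date"], sort=True).size()
    days = pd.DataFrame(
        {
            "n_fixes": n,
            "beeline_km": geodesy.gc_distance_deg(
                first["lon"], first["lat"], last["lon"], last["lat"]
            ),
        }
    )
    days.loc[days["n_fixes"] < 2, "beeline_km"] = np.nan

    if len(segments):
        seg = segments.copy()
        seg["date"] = pd.to_datetime(seg["t_start"]).dt.normalize()
        t_mid, lon_m, lat_m = _segment_midpoints(seg)
        seg["diurnal"] = solar_elevation(lon_m, lat_m, t_mid.to_numpy()) > night_elevation_deg
        trav = seg.loc[seg["is_travel"]].copy()
        if len(trav):
            trav["_diurnal_h"] = trav["duration_h"].where(trav["diurnal"], 0.0)
            g = trav.groupby(["bird_id", "date"])
            days["travel_h"] = g["duration_h"].sum()
            days["diurnal_h"] = g["_diurnal_h"].sum()
            days["mean_travel_speed_kmh"] = g["speed_kmh"].mean()
    for col in ("travel_h", "diurnal_h", "mean_travel_speed_kmh"):
        if col not in days.columns:
            days[col] = np.nan
    days["travel_h"] = days["travel_h"].fillna(0.0)
    days["diurnal_h"] = days["diurnal_h"].fillna(0.0)
    days["nocturnal_h"] = days["travel_h"] - days["diurnal_h"]

    days["day_class"] = np.where(days["beeline_km"] < stopover_km, "stopover", "travel")
    days.loc[days["n_fixes"] < 2, "day_class"] = "flagged"
    return days.reset_index()


def segment_stopovers(days: pd.DataFrame, fixes: pd.DataFrame) -> pd.DataFrame:
    """Collapse maximal runs of consecutive stop-over days into events.

    A run breaks whenever a calendar day is missing or classified other than
    'stopover'.  Event coordinates are the unweighted mean of all fixes
    recorded on the event's days.
    """
    fx = fixes.copy()
    fx["date"] = fx["t"].dt.normalize()
    events = []
    for bird, g in days.sort_values(["bird_id", "date"]).groupby("bird_id", sort=False):
        run: list[pd.Timestamp] = []
        prev = None
        for _, row in g.iterrows():
            is_stop = row["day_class"] == "stopover"
            contiguous = prev is not None and (row["date"] - prev) == pd.Timedelta(days=1)
            if is_stop and run and contiguous:
                run.append(row["date"])
            elif is_stop:
                if run:
                    events.append((bird, run))
                run = [row["date"]]
            else:
                if run:
                    events.append((bird, run))
                run = []
            prev = row["date"]
        if run:
            events.append((bird, run))
    rows = []
    for bird, run in events:
        sel = fx[(fx["bird_id"] == bird) & fx["date"].isin(run)]
        rows.append(
            {
                "bird_id": bird,
                "start_date": run[0],
                "end_date": run[-1],
                "duration_days": len(run),
                "mean_lon": sel["lon"].mean(),
                "mean_lat": sel["lat"].mean(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["bird_id", "start_date", "end_date", "duration_days", "mean_lon", "mean_lat"],
    )
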