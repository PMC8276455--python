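"""Biome annotation, desert-crossing extraction and ITF block matching.

Fixes are assigned one of four biome categories — ``desert`` (land with
maximum seasonal NDVI < 0.25), ``humid_forest`` (the Congo-Basin rainforest
polygon), ``sea`` (outside land polygons; islands below a size threshold
count as sea-crossing), and ``other`` (hospitable landscapes, mostly
savannah).  Category precedence at a single fix is sea > humid_forest >
desert > other: the sea test (land polygons) runs first, forest polygons
override NDVI, and the NDVI threshold applies to remaining land.

The Inter-Tropical Front (ITF) machinery matches trans-Sahelian travel days
to a decadal ITF table (latitude per 10-day period per 5-degree longitude
bin, bin centres -10 .. 35 degrees E).  Dekads follow the meteorological
calendar convention: days 1-10, 11-20, 21-end of each month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from . import geodesy
from .geodesy import signed_bearing

__all__ = [
    "Biome",
    "BiomeMap",
    "annotate_fixes",
    "modal_daily_biome",
    "longest_desert_run",
    "dekad_of",
    "filter_sahel_days",
    "match_itf",
    "ITF_LON_BINS",
]


class Biome(str, Enum):
    DESERT = "desert"
    HUMID_FOREST = "humid_forest"
    SEA = "sea"
    OTHER = "other"


#: Tie-break priority for the daily modal biome (higher = wins ties).
MODAL_TIE_PRIORITY = (Biome.DESERT, Biome.SEA, Biome.HUMID_FOREST, Biome.OTHER)

NDVI_DESERT_MAX = 0.25

#: Land polygons smaller than this (km^2) are ignored by the sea test, so
#: that fixes over small islands count as sea-crossings while Madagascar-sized
#: land masses count as land.
MIN_ISLAND_KM2 = 20_000.0

ITF_LON_BINS = np.arange(-10, 36, 5)
SAHEL_LON_RANGE = (-17.5, 37.5)
SAHEL_LAT_RANGE = (5.0, 15.0)
AUTUMN_SECTOR = (65.0, 125.0)  # degrees, due east
SPRING_SECTOR = (-125.0, -65.0)  # signed degrees, due west


def _poly_area_km2(poly: shapely.Polygon) -> float:
    """Approximate polygon area on the sphere via a local equal-area scale.

    Adequate for the island-size threshold (binary decision with a 20,000 km2
    margin), not for precise areal statistics.
    """
    lat0 = poly.centroid.y
    kx = 111.195 * np.cos(np.radians(lat0))
    ky = 111.195
    return float(poly.area * kx * ky)


@dataclass
class BiomeMap:
    """Biome lookup backed by either a category raster or NDVI + polygons.

    ``categories`` is a (lat, lon) array of category strings on the regular
    axes ``lons``/``lats`` (nearest-cell lookup).  Alternatively supply an
    ``ndvi`` raster plus ``land`` and ``forest`` shapely polygons; the sea /
    forest / NDVI precedence then applies.
    """

    lons: Optional[np.ndarray] = None
    lats: Optional[np.ndarray] = None
    categories: Optional[np.ndarray] = None
    ndvi: Optional[np.ndarray] = None
    land: Sequence[shapely.Polygon] = field(default_factory=list)
    forest: Sequence[shapely.Polygon] = field(default_factory=list)
    min_island_km2: float = MIN_ISLAND_KM2
    ndvi_desert_max: float = NDVI_DESERT_MAX
    season: str = ""

    def __post_init__(self):
        if self.categories is None and self.ndvi is None:
            raise ValueError("need a category raster or an NDVI raster")
        if self.lons is None or self.lats is None:
            raise ValueError("raster axes lons/lats are required")
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)

    def _cell_index(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        half_x = np.diff(self.lons).mean() / 2 if len(self.lons) > 1 else 0.0
        half_y = np.diff(self.lats).mean() / 2 if len(self.lats) > 1 else 0.0
        out = (
            (lon < self.lons[0] - half_x)
            | (lon > self.lons[-1] + half_x)
            | (lat < self.lats[0] - half_y)
            | (lat > self.lats[-1] + half_y)
        )
        if out.any():
            raise ValueError("query point outside biome map extent")
        i = np.clip(np.searchsorted(self.lats, lat) , 0, len(self.lats) - 1)
        # nearest-cell: compare to the neighbour below
        i = np.where(
            (i > 0) & (np.abs(lat - self.lats[np.maximum(i - 1, 0)]) <= np.abs(lat - self.lats[np.minimum(i, len(self.lats) - 1)])),
            i - 1,
            np.minimum(i, len(self.lats) - 1),
        )
        j = np.clip(np.searchsorted(self.lons, lon), 0, len(self.lons) - 1)
        j = np.where(
            (j > 0) & (np.abs(lon - self.lons[np.maximum(j - 1, 0)]) <= np.abs(lon - self.lons[np.minimum(j, len(self.lons) - 1)])),
            j - 1,
            np.minimum(j, len(self.lons) - 1),
        )
        return i, j

    def lookup(self, lon, lat) -> np.ndarray:
        """Biome category values for arrays of positions."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        if self.categories is not None:
            i, j = self._cell_index(lon, lat)
            return np.asarray(self.categories, dtype=object)[i, j]
        out = np.full(lon.shape, Biome.OTHER.value, dtype=object)
        big_land = [p for p in self.land if _poly_area_km2(p) >= self.min_island_km2]
        on_land = np.zeros(lon.shape, dtype=bool)
        for p in big_land:
            on_land |= shapely.contains_xy(p, lon, lat)
        out[~on_land] = Biome.SEA.value
        in_forest = np.zeros(lon.shape, dtype=bool)
        for p in self.forest:
            in_forest |= shapely.contains_xy(p, lon, lat)
        out[on_land & in_forest] = Biome.HUMID_FOREST.value
        i, j = self._cell_index(lon, lat)
        ndvi = np.asarray(self.ndvi, dtype=float)[i, j]
        desert = on_land & ~in_forest & (ndvi < self.ndvi_desert_max)
        out[desert] = Biome.DESERT.value
        return out


def annotate_fixes(fixes: pd.DataFrame, biome_map: BiomeMap) -> pd.DataFrame:
    """Return the fix table with a ``biome`` column appended."""
    out = fixes.copy()
    out["biome"] = biome_map.lookup(out["lon"].to_numpy(), out["lat"].to_numpy())
    return out


def modal_daily_biome(categories: Sequence[str]) -> str:
    """Most frequent category; ties break by desert > sea > humid_forest > other."""
    cats = pd.Series(list(categories))
    if cats.empty:
        raise ValueError("modal biome of an empty day")
    counts = cats.value_counts()
    best = counts.max()
    tied = set(counts[counts == best].index)
    for b in MODAL_TIE_PRIORITY:
        if b.value in tied:
            return b.value
    return counts.idxmax()  # non-standard category labels: plain mode


def longest_desert_run(fixes: pd.DataFrame) -> Optional[dict]:
    """Longest continuous run of desert-annotated fixes on a trip.

    Length is the cumulative great-circle step distance within the run; ties
    go to the earliest run.  Returns None when the trip has no desert fixes.
    """
    fx = fixes.sort_values("t").reset_index(drop=True)
    is_desert = (fx["biome"] == Biome.DESERT.value).to_numpy()
    if not is_desert.any():
        return None
    best = None
    i = 0
    n = len(fx)
    while i < n:
        if not is_desert[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_desert[j + 1]:
            j += 1
        length = float(
            geodesy.gc_distance_deg(
                fx["lon"].to_numpy()[i:j],
                fx["lat"].to_numpy()[i:j],
                fx["lon"].to_numpy()[i + 1 : j + 1],
                fx["lat"].to_numpy()[i + 1 : j + 1],
            ).sum()
        )
        if best is None or length > best["length_km"]:
            best = {
                "start": fx.loc[i].to_dict(),
                "end": fx.loc[j].to_dict(),
                "start_index": i,
                "end_index": j,
                "length_km": length,
            }
        i = j + 1
    return best


def dekad_of(dates) -> np.ndarray:
    """Dekad index 1..36 (days 1-10, 11-20, 21-end of each month)."""
    d = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]")))
    return ((d.month - 1) * 3 + np.minimum((d.day - 1) // 10, 2) + 1).to_numpy()


def filter_sahel_days(
    days: pd.DataFrame,
    fixes: pd.DataFrame,
    season: str,
    lon_range=SAHEL_LON_RANGE,
    lat_range=SAHEL_LAT_RANGE,
) -> pd.DataFrame:
    """Travel days qualifying for the ITF analysis.

    A day qualifies if it is a travel day, at least one of its fixes lies in
    the Sahel box (17.5 W - 37.5 E, 5 N - 15 N by default), and its daily
    bearing (first to last fix) falls in the seasonal sector: due east in
    autumn (65, 125), due west in spring (-125, -65) in the signed convention.

    Returns the qualifying day rows with a ``daily_bearing`` column.
    """
    fx = fixes.copy()
    fx["date"] = fx["t"].dt.normalize()
    g = fx.groupby(["bird_id", "date"], sort=True)
    first = g.first()
    last = g.last()
    brg = geodesy.initial_bearing_deg(first["lon"], first["lat"], last["lon"], last["lat"])
    daily = pd.DataFrame({"daily_bearing": brg}, index=first.index).reset_index()

    in_box = (
        (fx["lon"] >= lon_range[0])
        & (fx["lon"] <= lon_range[1])
        & (fx["lat"] >= lat_range[0])
        & (fx["lat"] <= lat_range[1])
    )
    box_days = fx.loc[in_box, ["bird_id", "date"]].drop_duplicates()

    out = days.merge(daily, on=["bird_id", "date"], how="left")
    out = out[out["day_class"] == "travel"]
    out = out.merge(box_days, on=["bird_id", "date"], how="inner")
    if season == "autumn":
        lo, hi = AUTUMN_SECTOR
        keep = (out["daily_bearing"] > lo) & (out["daily_bearing"] < hi)
    elif season == "spring":
        lo, hi = SPRING_SECTOR
        sb = signed_bearing(out["daily_bearing"].to_numpy())
        keep = (sb > lo) & (sb < hi)
    else:
        raise ValueError("season must be 'autumn' or 'spring'")
    out = out[keep].reset_index(drop=True)
    out["season"] = season
    return out


def match_itf(
    qualifying_days: pd.DataFrame,
    fixes: pd.DataFrame,
    itf: pd.DataFrame,
    lon_range=SAHEL_LON_RANGE,
    lat_range=SAHEL_LAT_RANGE,
):
    """Mean bird latitude per (bird, year, dekad, 5-degree lon bin), joined to
    the ITF table.

    Each qualifying day's in-box fixes are assigned individually to the
    nearest ITF longitude bin centre (a day spanning two bins contributes to
    both).  Blocks without a matching ITF record are dropped (count returned).

    ``itf`` columns: year, dekad, lon_bin, lat_itf.

    Returns
    -------
    (blocks, n_dropped)
    """
    fx = fixes.copy()
    fx["date"] = fx["t"].dt.normalize()
    keys = qualifying_days[["bird_id", "date"]].drop_duplicates()
    fx = fx.merge(keys, on=["bird_id", "date"], how="inner")
    in_box = (
        (fx["lon"] >= lon_range[0])
        & (fx["lon"] <= lon_range[1])
        & (fx["lat"] >= lat_range[0])
        & (fx["lat"] <= lat_range[1])
    )
    fx = fx[in_box].copy()
    bin_idx = np.round((fx["lon"].to_numpy() - ITF_LON_BINS[0]) / 5.0).astype(int)
    inside = (bin_idx >= 0) & (bin_idx < len(ITF_LON_BINS))
    fx = fx[inside].copy()
    fx["lon_bin"] = ITF_LON_BINS[bin_idx[inside]]
    fx["dekad"] = dekad_of(fx["date"].to_numpy())
    fx["year"] = fx["date"].dt.year

    season_map = None
    if "season" in qualifying_days.columns:
        season_map = qualifying_days.drop_duplicates(["bird_id", "date"])[
            ["bird_id", "date", "season"]
        ]
        fx = fx.merge(season_map, on=["bird_id", "date"], how="left")

    group_cols = ["bird_id", "year", "dekad", "lon_bin"]
    agg = {"lat": "mean"}
    blocks = fx.groupby(group_cols, as_index=False).agg(mean_lat_bird=("lat", "mean"))
    if season_map is not None:
        season_per_block = fx.groupby(group_cols)["season"].first().reset_index()
        blocks = blocks.merge(season_per_block, on=group_cols, how="left")
    merged = blocks.merge(itf, on=["year", "dekad", "lon_bin"], how="left")
    n_dropped = int(merged["lat_itf"].isna().sum())
    merged = merged.dropna(subset=["lat_itf"]).reset_index(drop=True)
    return merged, n_dropped
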