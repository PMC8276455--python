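"""Synthetic wind fields, biome maps, ITF tables and GPS tracks with known
ground truth.

The generators emulate the study conditions of a trans-African falcon
migration: hourly GPS fixes (optionally with up to 10-minute timestamp
jitter), mixed travel and stop-over days, seasonal goals (the Alegranza
colony in spring, the Madagascar coastline in autumn), a zonal wind field
with an ITF-like convergence line separating easterlies (Harmattan side)
from monsoon flow, and latitudinal biome bands.

The track simulator prescribes the ground-velocity side component directly —
sideward displacement rate equals ``(1 - c)`` times the sidewind relative to
the goal direction, where ``c`` is the compensation coefficient (c = 0 full
drift, c = 1 full compensation, c > 1 overcompensation, c < 0 overdrift) —
so the intended orientation category of every emitted segment is exact by
construction.  Heading-level aerodynamic realism is deliberately out of
scope: the generator provides classifier ground truth, not a flight model.

All generators are deterministic given their scenario and seed, with one
independent random stream per artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geodesy
from .context_annotation import Biome, BiomeMap
from .geodesy import GeoPoint
from .wind_field import WindGrid
from .wind_support import GoalSpec, classify_orientation_many, decompose, goal_bearing

__all__ = [
    "WindScenario",
    "BehaviourPolicy",
    "SyntheticTruth",
    "make_wind_grid",
    "simulate_track",
    "make_biome_bands",
    "make_itf_table",
    "make_regression_fixture",
    "DEFAULT_SAHEL_COEFFS",
]


@dataclass(frozen=True)
class WindScenario:
    """Zonal wind field with an ITF-like convergence line.

    ``u(lat, lon, t) = -U0 * tanh((lat - itf_lat(lon, t)) / width)``:
    easterlies (u < 0) north of the ITF line, westerly monsoon flow south of
    it, calm on the line itself.  The ITF latitude follows an annual cycle
    (northernmost in mid-August) plus a linear westward rise:
    ``itf_lat = itf_lat0 + itf_amp * cos(2 pi (doy - peak_doy)/365)
    + lon_slope * (lon - lon_ref)``.  ``v`` is a smooth bounded meridional
    perturbation of amplitude ``v_amp``.
    """

    lon_min: float = -40.0
    lon_max: float = 70.0
    lat_min: float = -35.0
    lat_max: float = 40.0
    dlon: float = 2.5
    dlat: float = 2.5
    t0: str = "2019-10-15"
    days: int = 60
    dt_hours: float = 6.0
    U0: float = 8.0  # m/s, peak zonal speed
    itf_lat0: float = 12.0  # degrees N at lon_ref on the annual mean
    itf_amp: float = 4.0  # degrees, seasonal modulation amplitude
    width: float = 3.0  # degrees, tanh transition half-width
    v_amp: float = 2.0  # m/s
    lon_slope: float = -0.1  # degrees lat per degree lon
    lon_ref: float = 10.0
    peak_doy: int = 228
    seed: int = 0

    def itf_lat(self, lon, t) -> np.ndarray:
        """ITF latitude (degrees N) at longitude(s) and UTC time(s)."""
        t = pd.DatetimeIndex(np.atleast_1d(np.asarray(t, dtype="datetime64[ns]")))
        doy = t.dayofyear.to_numpy(dtype=float)
        seasonal = self.itf_amp * np.cos(2 * np.pi * (doy - self.peak_doy) / 365.0)
        lat = self.itf_lat0 + seasonal + self.lon_slope * (np.asarray(lon, dtype=float) - self.lon_ref)
        if lat.ndim == 0:
            return float(lat)
        return lat


def make_wind_grid(scenario: WindScenario) -> WindGrid:
    """Deterministic wind grid realizing the scenario's analytic field."""
    lons = np.arange(scenario.lon_min, scenario.lon_max + scenario.dlon / 2, scenario.dlon)
    lats = np.arange(scenario.lat_min, scenario.lat_max + scenario.dlat / 2, scenario.dlat)
    t0 = np.datetime64(scenario.t0, "ns")
    n_t = int(scenario.days * 24 / scenario.dt_hours) + 1
    times = t0 + (np.arange(n_t) * scenario.dt_hours * 3600.0 * 1e9).astype("timedelta64[ns]")
    u = np.empty((n_t, len(lats), len(lons)))
    v = np.empty_like(u)
    for it, t in enumerate(times):
        itf = scenario.itf_lat(lons, t)  # per-longitude line
        u[it] = -scenario.U0 * np.tanh((lats[:, None] - itf[None, :]) / scenario.width)
        v[it] = (
            scenario.v_amp
            * np.sin(np.radians(lons[None, :] * 6.0))
            * np.cos(np.radians(lats[:, None] * 3.0))
        )
    return WindGrid(lons=lons, lats=lats, times=times, u=u, v=v)


@dataclass(frozen=True)
class BehaviourPolicy:
    """Prescribed orientation behaviour for the track simulator."""

    compensation: float  # c: 0 full drift, 1 full compensation
    airspeed_ms: float = 12.0  # forward ground speed along the goal bearing
    season: str = "autumn"
    goal: Optional[GoalSpec] = None
    daily_travel_h: int = 8
    travel_start_hour: int = 6  # UTC
    stopover_days: tuple[int, ...] = ()  # explicit day indices (0 = first day)
    stopover_prob: float = 0.0  # additional random per-day probability
    arrive_km: float = 100.0
    max_days: int = 60
    jitter_min: float = 0.0  # uniform timestamp jitter, minutes
    max_airspeed_ms: Optional[float] = None  # feasibility guard on implied airspeed

    def goal_spec(self) -> GoalSpec:
        return self.goal if self.goal is not None else GoalSpec.default(self.season)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the simulator for every emitted artifact."""

    segments: pd.DataFrame  # t_start, intended_ratio, sidewind, intended_category
    stopover_events: pd.DataFrame  # start_date, end_date, duration_days
    coefficients: dict = field(default_factory=dict)
    seed: int = 0


def _goal_point(pos: GeoPoint, spec: GoalSpec) -> GeoPoint:
    if spec.season == "spring":
        return spec.point
    dense = spec.densified()
    lons = np.array([q.lon for q in dense])
    lats = np.array([q.lat for q in dense])
    d = geodesy.gc_distance_deg(pos.lon, pos.lat, lons, lats)
    return dense[int(np.argmin(d))]


def simulate_track(
    policy: BehaviourPolicy,
    grid: WindGrid,
    start: GeoPoint,
    t0,
    seed: int = 0,
    bird_id: str = "B1",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one migration trip with hourly fixes and exact ground truth.

    Each travel hour the goal bearing g is recomputed, wind is sampled at the
    current position/time, and the ground velocity is built from a forward
    component of ``airspeed_ms`` along g plus a side component of
    ``(1 - c) * sidewind`` across g; the position then advances along the
    resulting bearing via the great-circle stepper.  Outside travel hours,
    and on injected stop-over days, the bird is stationary (hourly fixes are
    still emitted so that every day has a defined beeline).  The trip ends on
    arrival within ``arrive_km`` of the goal or after ``max_days``.
    """
    rng = np.random.default_rng(seed)
    spec = policy.goal_spec()
    c = policy.compensation
    t = pd.Timestamp(t0)
    pos = start
    fixes = []
    truth_rows = []
    stop_days: list[pd.Timestamp] = []
    arrived = False
    day_index = -1
    is_stop_day = False

    def emit(ts: pd.Timestamp, p: GeoPoint):
        jit = (
            pd.Timedelta(minutes=float(rng.uniform(-policy.jitter_min, policy.jitter_min)))
            if policy.jitter_min > 0
            else pd.Timedelta(0)
        )
        fixes.append({"bird_id": bird_id, "t": ts + jit, "lon": p.lon, "lat": p.lat})

    while not arrived:
        day = (t.normalize() - pd.Timestamp(t0).normalize()).days
        if day >= policy.max_days:
            break
        if day != day_index:
            day_index = day
            is_stop_day = day in policy.stopover_days or (
                policy.stopover_prob > 0 and rng.random() < policy.stopover_prob
            )
            if is_stop_day:
                stop_days.append(t.normalize())
        emit(t, pos)
        in_window = (
            policy.travel_start_hour
            <= t.hour
            < policy.travel_start_hour + policy.daily_travel_h
        )
        if in_window and not is_stop_day:
            g = goal_bearing(pos, spec.season, spec)
            u, v = grid.interp_uv(pos.lon, pos.lat, np.datetime64(t), strict=True)
            W = float(np.hypot(u[0], v[0]))
            dir_to = geodesy.normalize_bearing(float(np.degrees(np.arctan2(u[0], v[0]))))
            tail_g, side_g = decompose((W, dir_to), g)
            side_rate = (1.0 - c) * side_g
            forward = policy.airspeed_ms
            if policy.max_airspeed_ms is not None:
                implied = float(np.hypot(forward - tail_g, side_rate - side_g))
                if implied > policy.max_airspeed_ms:
                    raise RuntimeError(
                        f"infeasible step at {t} ({pos}): implied airspeed "
                        f"{implied:.1f} m/s exceeds {policy.max_airspeed_ms} m/s"
                    )
            speed_ms = float(np.hypot(forward, side_rate))
            brg = geodesy.normalize_bearing(g + float(np.degrees(np.arctan2(side_rate, forward))))
            step_km = speed_ms * 3.6  # one hour
            ratio, cat = classify_orientation_many([side_rate], [side_g])
            truth_rows.append(
                {
                    "bird_id": bird_id,
                    "t_start": t,
                    "intended_ratio": 1.0 - c,
                    "sidewind_gcr": float(side_g),
                    "intended_category": str(cat[0]),
                }
            )
            pos = geodesy.destination(pos, brg, step_km)
            goal_pt = _goal_point(pos, spec)
            if geodesy.gc_distance(pos, goal_pt) <= policy.arrive_km:
                arrived = True
                emit(t + pd.Timedelta(hours=1), pos)
        t = t + pd.Timedelta(hours=1)

    fixes_df = pd.DataFrame(fixes).sort_values("t").reset_index(drop=True)
    events = []
    if stop_days:
        run = [stop_days[0]]
        for d in stop_days[1:]:
            if (d - run[-1]) == pd.Timedelta(days=1):
                run.append(d)
            else:
                events.append(run)
                run = [d]
        events.append(run)
    ev = pd.DataFrame(
        [
            {
                "bird_id": bird_id,
                "start_date": r[0],
                "end_date": r[-1],
                "duration_days": len(r),
            }
            for r in events
        ],
        columns=["bird_id", "start_date", "end_date", "duration_days"],
    )
    truth = SyntheticTruth(
        segments=pd.DataFrame(
            truth_rows,
            columns=["bird_id", "t_start", "intended_ratio", "sidewind_gcr", "intended_category"],
        ),
        stopover_events=ev,
        seed=seed,
    )
    return fixes_df, truth


def make_biome_bands(
    lon_range=( -25.0, 60.0),
    lat_range=(-35.0, 40.0),
    dlon: float = 0.5,
    dlat: float = 0.5,
    bands: Sequence[tuple[float, float, str]] = (
        (-35.0, -5.0, Biome.OTHER.value),
        (-5.0, 5.0, Biome.HUMID_FOREST.value),
        (5.0, 15.0, Biome.OTHER.value),
        (15.0, 32.0, Biome.DESERT.value),
        (32.0, 40.0, Biome.OTHER.value),
    ),
    sea_rects: Sequence[tuple[float, float, float, float]] = ((35.0, 60.0, -30.0, -5.0),),
) -> BiomeMap:
    """Latitudinal biome bands plus sea rectangles, as a category raster.

    Bands are half-open ``[south, north)`` and must partition the latitude
    range without overlap; ``sea_rects`` (lon_min, lon_max, lat_min, lat_max)
    override the bands.  The defaults sketch an African transect: savannah,
    Congo-like forest band, Sahel, Sahara-like desert band, and an Indian
    Ocean rectangle.
    """
    b = sorted(bands)
    for (s1, n1, _), (s2, n2, _) in zip(b[:-1], b[1:]):
        if n1 > s2:
            raise ValueError("biome bands overlap")
        if n1 < s2:
            raise ValueError("biome bands leave a gap")
    if b[0][0] > lat_range[0] or b[-1][1] < lat_range[1]:
        raise ValueError("biome bands do not cover the latitude range")
    lons = np.arange(lon_range[0], lon_range[1] + dlon / 2, dlon)
    lats = np.arange(lat_range[0], lat_range[1] + dlat / 2, dlat)
    cats = np.full((len(lats), len(lons)), Biome.OTHER.value, dtype=object)
    for south, north, name in b:
        rows = (lats >= south) & (lats < north)
        cats[rows, :] = name
    for lo, hi, s, n in sea_rects:
        rows = (lats >= s) & (lats <= n)
        cols = (lons >= lo) & (lons <= hi)
        cats[np.ix_(rows, cols)] = Biome.SEA.value
    return BiomeMap(lons=lons, lats=lats, categories=cats)


def make_itf_table(
    scenario: WindScenario,
    years: Sequence[int],
    noise_sd: float = 0.0,
    seed: int = 0,
    dekads: Sequence[int] = tuple(range(10, 31)),  # April .. October
) -> pd.DataFrame:
    """Decadal ITF latitude table (year, dekad, lon_bin, lat_itf).

    Latitudes are sampled from the scenario's analytic ITF line at the
    mid-dekad date of each period, at 5-degree longitude bin centres from
    -10 to 35, plus seeded Gaussian noise of ``noise_sd`` degrees.
    """
    rng = np.random.default_rng(seed)
    bins = np.arange(-10, 36, 5)
    rows = []
    for year in years:
        for dk in dekads:
            month = (dk - 1) // 3 + 1
            day = [5, 15, 25][(dk - 1) % 3]
            date = pd.Timestamp(year=year, month=month, day=day)
            lat = scenario.itf_lat(bins.astype(float), np.datetime64(date))
            lat = np.atleast_1d(lat) + rng.normal(0.0, noise_sd, size=len(bins))
            for b, l in zip(bins, lat):
                rows.append({"year": year, "dekad": dk, "lon_bin": int(b), "lat_itf": float(l)})
    return pd.DataFrame(rows)


#: Default generating coefficients for the trans-Sahelian latitude fixture:
#: block latitude as a function of ITF latitude, longitude, season and their
#: interactions, with magnitudes typical of Sahel-corridor tracking data
#: (latitude in degrees N, longitude in degrees E).
DEFAULT_SAHEL_COEFFS = {
    "Intercept": 9.530,
    "lat_itf": 0.228,
    "long": -0.345,
    "spring": 1.679,
    "lat_itf:long": 0.018,
    "lat_itf:spring": -0.232,
    "long:spring": 0.217,
    "lat_itf:long:spring": -0.012,
}


def make_regression_fixture(
    coefficients: Optional[dict] = None,
    n: int = 300,
    sigma: float = 1.5,
    n_individuals: int = 19,
    group_sd: float = 1.0,
    year_sd: float = 0.0,
    n_years: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Gaussian regression table with random intercepts and known coefficients.

    Columns: ``lat_itf`` (degrees N), ``long`` (degrees E), ``season``,
    ``individual``, ``year`` and the response ``mean_lat_bird`` built from the
    linear predictor defined by ``coefficients`` (keys as in
    :data:`DEFAULT_SAHEL_COEFFS`; missing keys contribute zero), plus
    individual (and optional year) random intercepts and N(0, sigma) noise.
    """
    if coefficients is None:
        coefficients = DEFAULT_SAHEL_COEFFS
    rng = np.random.default_rng(seed)
    lat_itf = rng.uniform(8.0, 18.0, n)
    long = rng.uniform(-10.0, 35.0, n)
    spring = rng.integers(0, 2, n).astype(float)
    individual = rng.integers(0, n_individuals, n)
    year = rng.integers(0, n_years, n)
    u_ind = rng.normal(0.0, group_sd, n_individuals)
    u_yr = rng.normal(0.0, year_sd, n_years)

    def coef(name: str) -> float:
        return float(coefficients.get(name, 0.0))

    eta = (
        coef("Intercept")
        + coef("lat_itf") * lat_itf
        + coef("long") * long
        + coef("spring") * spring
        + coef("lat_itf:long") * lat_itf * long
        + coef("lat_itf:spring") * lat_itf * spring
        + coef("long:spring") * long * spring
        + coef("lat_itf:long:spring") * lat_itf * long * spring
    )
    y = eta + u_ind[individual] + u_yr[year] + rng.normal(0.0, sigma, n)
    df = pd.DataFrame(
        {
            "mean_lat_bird": y,
            "lat_itf": lat_itf,
            "long": long,
            "season": np.where(spring > 0, "spring", "autumn"),
            "individual": [f"B{i:02d}" for i in individual],
            "year": 2012 + year,
        }
    )
    truth = SyntheticTruth(
        segments=pd.DataFrame(),
        stopover_events=pd.DataFrame(),
        coefficients={**coefficients, "sigma": sigma, "group_sd": group_sd, "year_sd": year_sd},
        seed=seed,
    )
    return df, truth
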