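"""Trip-level performance metrics and paired seasonal comparisons.

Detour extent is the ratio of the cumulative distance travelled across all
travel segments on travel days over the great-circle distance from the first
to the last fix of the trip; a perfectly straight trip has detour extent 1.

Seasonal comparisons use paired two-sided t-tests on the first recorded trip
of each individual in each season, with Holm adjustment across the metric
family (the study reports adjusted p-values without naming the method; Holm
is conservative and assumption-free, and the method is configurable).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import geodesy

__all__ = ["trip_summary", "infer_trip_bounds", "paired_seasonal_tests", "PAIRED_METRICS"]

#: Default metric family compared between seasons.
PAIRED_METRICS = (
    "detour_extent",
    "duration_days",
    "stopover_days",
    "travel_days",
    "diurnal_hours",
    "nocturnal_hours",
    "mean_daily_distance_km",
    "mean_daily_travel_h",
    "mean_daily_tailwind_track",
    "mean_daily_tailwind_gcr",
)


def infer_trip_bounds(days: pd.DataFrame) -> pd.DataFrame:
    """Default trip boundaries: first and last travel day per bird.

    The study's colony-specific departure rules depend on the geography of
    the real data; callers with richer context should supply explicit bounds.
    """
    trav = days[days["day_class"] == "travel"]
    g = trav.groupby("bird_id")["date"]
    return pd.DataFrame({"start_date": g.min(), "end_date": g.max()}).reset_index()


def trip_summary(
    days: pd.DataFrame,
    segments: pd.DataFrame,
    fixes: pd.DataFrame,
    daily_wind: Optional[pd.DataFrame] = None,
) -> dict:
    """Performance metrics for one trip (caller passes that trip's rows only).

    ``duration_days`` counts inclusive calendar days from the first to the
    last day; ``cumulative_travel_km`` sums travel-segment step lengths on
    travel days only; daily means average over travel days.
    """
    if len(fixes) < 2:
        raise ValueError("a trip needs at least 2 fixes")
    fx = fixes.sort_values("t")
    p_first = fx.iloc[0]
    p_last = fx.iloc[-1]
    gc_km = float(
        geodesy.gc_distance_deg(p_first["lon"], p_first["lat"], p_last["lon"], p_last["lat"])
    )

    seg = segments.copy()
    seg["date"] = pd.to_datetime(seg["t_start"]).dt.normalize()
    travel_days_idx = days.loc[days["day_class"] == "travel", ["bird_id", "date"]]
    seg = seg.merge(travel_days_idx, on=["bird_id", "date"], how="inner")
    cumulative = float(seg.loc[seg["is_travel"], "step_km"].sum())

    d = days.sort_values("date")
    n_travel = int((d["day_class"] == "travel").sum())
    n_stop = int((d["day_class"] == "stopover").sum())
    n_flagged = int((d["day_class"] == "flagged").sum())
    duration = int((d["date"].iloc[-1] - d["date"].iloc[0]).days) + 1
    trav = d[d["day_class"] == "travel"]

    out = {
        "cumulative_travel_km": cumulative,
        "gc_first_last_km": gc_km,
        "detour_extent": cumulative / gc_km if gc_km > 0 else np.nan,
        "duration_days": duration,
        "travel_days": n_travel,
        "stopover_days": n_stop,
        "flagged_days": n_flagged,
        "diurnal_hours": float(d["diurnal_h"].sum()),
        "nocturnal_hours": float(d["nocturnal_h"].sum()),
        "mean_daily_distance_km": float(trav["beeline_km"].mean()),
        "mean_daily_travel_h": float(trav["travel_h"].mean()),
    }
    if daily_wind is not None and len(daily_wind):
        dw = daily_wind.merge(travel_days_idx, on=["bird_id", "date"], how="inner")
        out["mean_daily_tailwind_track"] = float(dw["tailwind_track"].mean())
        out["mean_daily_tailwind_gcr"] = float(dw["tailwind_gcr"].mean())
    return out


def paired_seasonal_tests(
    trips: pd.DataFrame,
    metrics: Sequence[str] = PAIRED_METRICS,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Paired two-sided t-tests of autumn vs spring trip metrics.

    Uses the first recorded trip per bird and season (earliest ``year``, then
    ``start_date`` when present); birds missing a season are excluded.  At
    least 3 complete pairs are required.  A zero-variance nonzero difference
    is degenerate and reported with infinite t (flagged); identical seasonal
    values give t = 0, p = 1.

    Returns one row per metric: n pairs, seasonal means, t, df, raw and
    adjusted p-values.
    """
    metrics = [m for m in metrics if m in trips.columns]
    if not metrics:
        raise ValueError("no requested metric column present")
    sort_cols = [c for c in ("year", "start_date") if c in trips.columns]
    first = (
        trips.sort_values(sort_cols) if sort_cols else trips
    ).groupby(["bird_id", "season"], as_index=False).first()
    wide = first.pivot(index="bird_id", columns="season", values=metrics)
    rows = []
    for m in metrics:
        sub = wide[m].dropna(subset=["autumn", "spring"])
        n = len(sub)
        if n < 3:
            raise ValueError(f"metric {m!r}: fewer than 3 complete seasonal pairs")
        a = sub["autumn"].to_numpy(float)
        s = sub["spring"].to_numpy(float)
        diff = a - s
        degenerate = False
        if np.std(diff, ddof=1) == 0.0:
            if np.all(diff == 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(diff.mean()) * np.inf), 0.0
                degenerate = True
        else:
            res = stats.ttest_rel(a, s)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "metric": m,
                "n_pairs": n,
                "mean_autumn": float(a.mean()),
                "mean_spring": float(s.mean()),
                "t": t,
                "df": n - 1,
                "p_raw": p,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method=adjust)[1]
    return out
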