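# Methods

This note documents the models, conventions and numerical choices behind
`windrift`, and what the synthetic-data validation does and does not show.

## Geodesy

All geometry is spherical with R = 6371.0088 km (IUGG mean radius).
Distances use the haversine form, which is numerically stable at the small
separations that dominate hourly GPS steps; at flyway scale the spherical
approximation deviates from ellipsoidal geodesics by a few km, far below
track noise. Bearings are stored in [0, 360) with a signed view in
(−180, 180] for westward-sector filters (the direction conventions used for
the Sahel corridor mix both).

"Nearest point on a coastline" is computed by densifying the boundary ring to
≤ 10 km vertex spacing (great-circle interpolation between vertices) and
taking the arg-min vertex. This avoids geodesic point-to-arc minimization;
the error is bounded by the densification spacing, which is negligible
against a 2.5° wind grid. The built-in Madagascar outline is a coarse
(~15-vertex) approximation intended for simulation and testing; production
analyses should supply a real coastline GeoJSON.

## Track pipeline

* **Resampling.** One fix per whole UTC hour, choosing the candidate nearest
  in time within ±10 min (earlier fix wins exact ties; each source fix is
  used at most once). Consecutive filled hour marks are therefore
  60 ± 20 min apart.
* **Segments.** Movement statistics are computed from each resampled fix to
  the next. Pairs separated by more than 1.2 h (a configurable gap cap)
  break the hourly track rather than being summed into travel time.
  `is_travel` applies the 5 km/h hourly speed threshold separating directed
  movement from localized foraging/resting.
* **Days.** The daily beeline is the great-circle distance from the first to
  the last fix of the UTC calendar day; days with beeline < 100 km are
  stop-over days. Segments are assigned to the calendar day of their start
  fix (deterministic; midnight-spanning segments are rare at hourly
  resolution). Days with fewer than two fixes have no beeline and are
  flagged rather than classified. The diurnal/nocturnal split evaluates
  geometric solar elevation (low-precision Fourier expansion for declination
  and the equation of time, accurate to a fraction of a degree) at the
  segment's temporal and spatial midpoint, with the day/night boundary at 0°
  elevation (parameter-free; configurable).
* **Stop-over events** are maximal runs of consecutive stop-over days; their
  coordinates are unweighted means over the event's fixes.

All timestamps are UTC; no local-time conversion is performed (solar
elevation already encodes local day/night).

## Wind annotation

Wind grids are regular in (time, lat, lon); u and v are interpolated
trilinearly (scipy `RegularGridInterpolator`) and speed/direction are derived
from the interpolated *components*, never interpolated themselves. Queries
outside the grid raise (no extrapolation); longitudes are not wrapped across
the antimeridian, which an African-domain grid never crosses. A single
pressure level is used (850 mb sits near typical falcon flight altitudes);
there is no vertical interpolation.

Wind direction follows the TOWARD convention (vector heading of (u, v)), so
a wind whose heading equals the travel bearing is a pure tailwind — the sign
convention under which LWGI = cos θ − cos β yields positive gains for
tailwind improvements. Wind is sampled at each segment's start fix
(position and time); a midpoint option is provided. θ and β are folded into
[0°, 180°] before the cosine (cos is even, so this is cosmetic). LWGI is
undefined at W = 0 (the defining ratio divides by W) and such segments are
excluded from daily LWGI means. Daily wind summaries average over a day's
travel segments only. Per-segment daily LWGI means are provided as a
convenience beyond the core per-segment index.

Sideward displacement rate and sidewind are both signed positive to the
*right* of the reference bearing, so drifting with the wind gives a positive
ratio regardless of which side the wind pushes. Classification thresholds
(−0.2, 0.2, 0.8, 1.2) are open intervals in their usual statement; boundary
ratios — a measure-zero event — fall deterministically to the lower-ratio
category. Ratios are not classified when |sidewind| < 0.5 m/s.

## Biomes and the ITF

Category precedence at a fix is sea > humid forest > desert > other: the sea
test (land polygons) runs first, forest polygons override NDVI, and the
NDVI < 0.25 desert rule applies to the remaining land. Land polygons smaller
than 20,000 km² are ignored by the sea test so that fixes over small islands
count as sea-crossings while Madagascar-sized land masses count as land
(threshold configurable). Polygon areas use a local equal-area scale at the
polygon centroid — adequate for a binary size decision, not for areal
statistics. Daily modal biomes break ties by desert > sea > humid forest >
other.

Dekads follow the meteorological calendar convention (days 1–10, 11–20,
21–end of month). ITF longitude bins are 5° wide, centred −10° … 35°E. A
travel day qualifies for the ITF analysis if its daily bearing (first to
last fix) lies in the seasonal sector — due east (65°, 125°) when heading to
the winter range, due west (−125°, −65°) on return — and it has fixes inside
the Sahel box (17.5°W–37.5°E, 5°N–15°N). Fixes are assigned to bins
individually, so a day spanning two bins contributes to both; blocks are
means per (bird, year, dekad, bin), joined to the ITF table, with unmatched
blocks dropped and counted.

## Trip metrics and seasonal comparisons

Detour extent = cumulative travel-segment distance on travel days ÷
great-circle distance between the trip's first and last fix. Trip duration
counts inclusive calendar days. Trip boundaries are caller-supplied;
`infer_trip_bounds` defaults to each bird's first and last travel day
(colony-specific departure rules are data-specific and out of scope).
Seasonal comparisons are paired two-sided t-tests on the first recorded trip
per bird and season, Holm-adjusted across the metric family (the adjustment
method is configurable). Zero-variance nonzero differences are degenerate
and reported with infinite t and a flag.

## Mixed models

Candidate models are Gaussian linear mixed models (identity link) with
random intercepts, estimated by maximum likelihood — not REML — because the
candidate sets differ in fixed effects and REML likelihoods are not
comparable across fixed-effect structures. Estimation delegates to
statsmodels `MixedLM`; two or more random factors (individual + year) are
fitted as crossed random intercepts via variance components on a single
grouping, and specifications without random factors fall back to OLS (whose
ML log-likelihood is continuous with the mixed case at zero variance).

The parameter count k = fixed coefficients + random-intercept variances +
residual variance, the convention behind the df column of mixed-model AIC
tables (intercept-only with one random intercept: k = 3). AICc = AIC +
2k(k+1)/(n−k−1) is used for trip-level and Sahel-block sets; the daily-level
sets use plain AIC, where the travel-day sample is large enough for the
correction to vanish. Akaike weights are exp(−Δ/2) normalized over the set,
and the selected model is the most parsimonious (smallest k) among those
with Δ < 2, ties broken by smallest Δ — a deterministic rule.

Coefficient p-values use a residual-df t approximation (df = n − p). This
is a simple stand-in for Satterthwaite-style degrees of freedom and is
accurate when group counts are not tiny; ranking and weights do not depend
on it. Partial R² follows the variance-decomposition (marginal/conditional)
convention: r²_fixed = var(Xβ̂)/total, r²_random = random-variance share,
r²_full their sum, with total = var(Xβ̂) + Σ random variances + residual
variance. Published mixed-model R² estimators differ in detail; numerical
agreement with other conventions is not guaranteed.

Positively skewed duration-type responses (trip duration, travel days,
stop-over days, daily distance, daily mean speed) are log-transformed before
fitting.

## Synthetic data: what it emulates and what it does not

The wind generator realizes u(lat, lon, t) = −U0·tanh((lat − itf_lat)/width)
with an ITF line that follows an annual cycle (northernmost in mid-August)
plus a linear westward rise, and a smooth bounded meridional component —
calm on the line, easterlies to the north, monsoon-like westerlies to the
south. Defaults (U0 = 8 m/s, itf_lat0 = 12°N, amplitude 4°, half-width 3°,
v_amp = 2 m/s, 2.5° / 6-hourly grid) give hourly sidewinds of a few m/s
along a trans-African track, the regime in which drift classification is
meaningful.

The track simulator prescribes the ground-velocity side component directly:
sideward rate = (1 − c) × sidewind relative to the goal bearing, forward
speed fixed (12 m/s default, ~8 travel hours per day starting 06:00 UTC,
hourly fixes around the clock so every day has a defined beeline; ≤ ±10 min
optional timestamp jitter; stop-over days injected by schedule or per-day
probability). This makes the intended orientation category of every segment
exact by construction — the point is classifier ground truth, not flight
realism. Consequently, passing the recovery tests shows the decomposition,
ratio and classification chain is self-consistent end-to-end; it does not
validate heading reconstruction, airspeed estimation, thermalling behaviour,
GPS error models, or any aerodynamic constraint linking wind to achievable
ground speed. Real tracks also violate the simulator's clean travel-window
structure (foraging loops, partial days), which the 5 km/h and 100 km
thresholds absorb only approximately.

Regression fixtures draw covariates uniformly over Sahel-corridor ranges
(ITF latitude 8–18°N, longitude −10–35°E), with default generating
coefficients of magnitudes typical for block latitudes along that corridor,
individual random intercepts (sd 1.0°) and residual sd 1.5°. Each generator
uses its own seeded stream, so regenerating one fixture never shifts
another.

## Known limitations

* Vertex (not point-to-arc) nearest-boundary search; error ≤ densification
  spacing.
* No GPS outlier filtering beyond monotone-time enforcement; no behavioural
  state models.
* Biome maps are static per season; no NDVI time-series processing.
* The ITF block analysis assumes the ITF table covers the days analysed;
  late-autumn gaps in real ITF products simply drop blocks.
* Satterthwaite df and the published partial-R² estimator are approximated
  as described above.
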