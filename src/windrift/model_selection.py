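"""Gaussian linear mixed models, AIC(c) ranking, Akaike weights, partial R^2.

Candidate models are Gaussian GLMMs (identity link) with random intercepts
for individual and, where stated, year.  All likelihoods are maximum
likelihood (not REML) because the candidate sets differ in fixed effects, and
REML likelihoods are not comparable across fixed-effect structures.

The parameter count k includes fixed-effect coefficients, random-intercept
variances and the residual variance, matching the conventional df column of
mixed-model AIC tables (e.g. an intercept-only model with one random
intercept has k = 3).

Estimation delegates to statsmodels ``MixedLM`` (OLS when no random factors
are requested); two or more random factors are fitted as crossed random
intercepts via variance components on a single grouping.  Coefficient
p-values use a residual-degrees-of-freedom t approximation
(df = n - n_fixed), a simple stand-in for Satterthwaite-style df that is
accurate away from tiny group counts.

Partial R^2 follows the variance-decomposition (marginal/conditional)
convention: r2_fixed = var(X beta) / total, r2_random = random-intercept
variance share, r2_full = their sum, with
total = var(X beta) + sum(random variances) + residual variance.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit_lmm",
    "aicc",
    "aic",
    "rank_models",
    "partial_r2",
    "build_candidate_sets",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed-effect formula RHS, random
    intercept factors, information criterion and optional log-transform."""

    response: str
    fixed: str = "1"
    random: tuple[str, ...] = ()
    log_response: bool = False
    criterion: str = "aicc"  # 'aicc' or 'aic'
    name: Optional[str] = None

    @property
    def label(self) -> str:
        return self.name or f"~ {self.fixed}"


@dataclass
class FittedModel:
    spec: ModelSpec
    loglik: float
    k: int
    nobs: int
    coef: pd.DataFrame  # estimate, se, df, t, p
    var_fixed: float
    var_random: dict
    var_resid: float
    rows: tuple = field(repr=False, default=())

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.nobs)

    def score(self) -> float:
        return self.aicc if self.spec.criterion == "aicc" else self.aic


def aic(loglik: float, k: int) -> float:
    """Akaike's information criterion, -2 logLik + 2k."""
    return -2.0 * loglik + 2.0 * k


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n - k - 1); needs n > k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return aic(loglik, k) + 2.0 * k * (k + 1) / (n - k - 1)


_TOKEN = re.compile(r"[A-Za-z_]\w*")


def _referenced_columns(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    cols = {t for t in _TOKEN.findall(spec.fixed) if t in data.columns}
    cols.add(spec.response)
    cols.update(spec.random)
    return sorted(cols)


def _coef_table(params, bse, n: int) -> pd.DataFrame:
    df_resid = max(n - len(params), 1)
    t = params / bse
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    return pd.DataFrame(
        {"estimate": params, "se": bse, "df": float(df_resid), "t": t, "p": p}
    )


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one candidate by maximum likelihood on complete-case rows.

    A singular random-intercept variance is retained at (near) zero with a
    warning; a rank-deficient fixed-effect design raises.
    """
    cols = _referenced_columns(spec, data)
    df = data.dropna(subset=cols).copy()
    if df.empty:
        raise ValueError("no complete-case rows")
    y = df[spec.response].astype(float)
    if spec.log_response:
        if (y <= 0).any():
            raise ValueError(f"log-transform of non-positive {spec.response!r}")
        y = np.log(y)
    df["_y"] = y
    formula = f"_y ~ {spec.fixed}"
    n = len(df)
    rows = tuple(df.index)

    for g in spec.random:
        if df[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} has < 2 levels")

    if not spec.random:
        res = smf.ols(formula, data=df).fit()
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise ValueError("rank-deficient fixed-effect design")
        k = len(res.params) + 1
        var_fixed = float(np.var(res.fittedvalues))
        var_resid = float(res.ssr / n)  # ML residual variance
        coef = _coef_table(res.params, res.bse, n)
        return FittedModel(spec, float(res.llf), k, n, coef, var_fixed, {}, var_resid, rows)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(spec.random) == 1:
            g = spec.random[0]
            md = smf.mixedlm(formula, data=df, groups=df[g], re_formula="1")
            res = md.fit(reml=False)
            var_random = {g: float(res.cov_re.iloc[0, 0])}
        else:
            vc = {g: f"0 + C({g})" for g in spec.random}
            md = smf.mixedlm(
                formula,
                data=df,
                groups=np.ones(n),
                vc_formula=vc,
                re_formula="0",
            )
            res = md.fit(reml=False)
            names = md.exog_vc.names
            var_random = {g: float(v) for g, v in zip(names, res.vcomp)}
    if np.linalg.matrix_rank(md.exog) < md.exog.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    if any(v < 1e-8 for v in var_random.values()):
        warnings.warn("singular fit: a random-intercept variance is ~0", stacklevel=2)

    p_fixed = len(res.fe_params)
    k = p_fixed + len(spec.random) + 1
    var_fixed = float(np.var(md.exog @ res.fe_params.to_numpy()))
    var_resid = float(res.scale)
    coef = _coef_table(res.fe_params, res.bse_fe, n)
    return FittedModel(
        spec, float(res.llf), k, n, coef, var_fixed, var_random, var_resid, rows
    )


def partial_r2(fit: FittedModel) -> tuple[float, float, float]:
    """(r2_full, r2_fixed, r2_random) by variance decomposition."""
    total = fit.var_fixed + sum(fit.var_random.values()) + fit.var_resid
    if total <= 0:
        raise ValueError("zero total variance")
    r2_fixed = fit.var_fixed / total
    r2_random = sum(fit.var_random.values()) / total
    return r2_fixed + r2_random, r2_fixed, r2_random


def rank_models(fits: Sequence[FittedModel]):
    """Rank a candidate set by AIC(c); return (table, best).

    All candidates must be fitted on identical rows.  The best model is the
    most parsimonious (fewest parameters k) among those with delta < 2, ties
    broken by smallest delta.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 candidates to rank")
    rows0 = fits[0].rows
    for f in fits[1:]:
        if f.rows != rows0:
            raise ValueError("candidates were fitted on differing row sets")
    scores = np.array([f.score() for f in fits])
    delta = scores - scores.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    r2 = [partial_r2(f) for f in fits]
    table = pd.DataFrame(
        {
            "model": [f.spec.label for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "score": scores,
            "delta": delta,
            "weight": w,
            "r2_full": [x[0] for x in r2],
            "r2_fixed": [x[1] for x in r2],
            "r2_random": [x[2] for x in r2],
        }
    ).sort_values("delta", kind="stable").reset_index(drop=True)
    close = [(f.k, d, i) for i, (f, d) in enumerate(zip(fits, delta)) if d < 2.0]
    best_idx = min(close)[2]
    return table, fits[best_idx]


# ---------------------------------------------------------------------------
# candidate sets

#: Sahel-latitude candidate structures (response: mean bird latitude per
#: spatiotemporal block; predictors: lon bin, ITF latitude, season; random
#: intercept per individual).
SAHEL_FIXED = (
    "long * lat_itf * season",
    "long * season",
    "lat_itf + long",
    "long * lat_itf",
    "long",
    "long + season",
    "lat_itf * season",
    "lat_itf + season",
    "lat_itf",
    "season",
    "1",
)

TRIP_FIXED = (
    "detour_extent * season",
    "detour_extent + season",
    "detour_extent",
    "season",
    "1",
)

TRIP_RESPONSES = (
    ("duration_days", True),
    ("travel_days", True),
    ("stopover_days", True),
    ("mean_daily_tailwind_track", False),
)

#: Daily-performance candidate structures (exhaustive set: wind components
#: along the realized track, daily travel time, biome, season, their additive
#: effects and the stated interactions).
DAILY_FIXED = (
    "(tailwind_track + abs(sidewind_track)) * travel_hrs * biome",
    "(tailwind_track + abs(sidewind_track)) * biome + season",
    "biome * travel_hrs",
    "(tailwind_track + abs(sidewind_track)) * travel_hrs + biome",
    "travel_hrs * abs(sidewind_track)",
    "tailwind_track * travel_hrs",
    "abs(sidewind_track) + travel_hrs",
    "biome + abs(sidewind_track)",
    "season + abs(sidewind_track)",
    "season + biome + travel_hrs",
    "season * tailwind_track",
    "(tailwind_track + abs(sidewind_track)) * season",
    "biome + tailwind_track + abs(sidewind_track)",
    "tailwind_track + abs(sidewind_track)",
    "season + tailwind_track + biome",
    "season + tailwind_track",
    "season + abs(sidewind_track) + travel_hrs",
    "biome + travel_hrs",
    "abs(sidewind_track)",
    "(tailwind_track + abs(sidewind_track)) * travel_hrs * season",
    "(tailwind_track + abs(sidewind_track)) * travel_hrs + season",
    "(tailwind_track + abs(sidewind_track)) * biome * season",
    "biome * tailwind_track",
    "travel_hrs + tailwind_track + abs(sidewind_track)",
    "(tailwind_track + abs(sidewind_track)) * biome",
    "season * travel_hrs",
    "(tailwind_track + abs(sidewind_track)) * travel_hrs",
    "season * abs(sidewind_track)",
    "tailwind_track * abs(sidewind_track)",
    "biome + tailwind_track + travel_hrs",
    "season * biome",
    "biome + tailwind_track",
    "season + travel_hrs",
    "season + biome + abs(sidewind_track)",
    "tailwind_track + travel_hrs",
    "biome * abs(sidewind_track)",
    "biome",
    "travel_hrs",
    "season + tailwind_track + travel_hrs",
    "season + tailwind_track + abs(sidewind_track)",
    "season + biome",
    "tailwind_track",
    "season",
    "1",
)

DAILY_RESPONSES = (
    ("daily_distance_km", True),
    ("mean_travel_speed_kmh", True),
)


def build_candidate_sets(context: str) -> list[ModelSpec]:
    """Enumerate the candidate :class:`ModelSpec` list for a given analysis.

    ``sahel_latitude``: 11 structures for mean block latitude, random
    intercept per individual, AICc ranking.

    ``trip_level``: detour-extent / season structures for the four trip
    responses (durations log-transformed, which corrects their positive
    skew), random intercepts for individual and year, AICc (n = 75 trips).

    ``daily_level``: the exhaustive daily-performance set for log daily
    distance and log daily mean travel speed, random intercepts for
    individual and year, plain AIC (the travel-day sample is large enough
    that the small-sample correction is negligible).
    """
    if context == "sahel_latitude":
        return [
            ModelSpec(
                response="mean_lat_bird",
                fixed=f,
                random=("individual",),
                criterion="aicc",
            )
            for f in SAHEL_FIXED
        ]
    if context == "trip_level":
        return [
            ModelSpec(
                response=r,
                fixed=f,
                random=("individual", "year"),
                log_response=log,
                criterion="aicc",
            )
            for r, log in TRIP_RESPONSES
            for f in TRIP_FIXED
        ]
    if context == "daily_level":
        return [
            ModelSpec(
                response=r,
                fixed=f,
                random=("individual", "year"),
                log_response=log,
                criterion="aic",
            )
            for r, log in DAILY_RESPONSES
            for f in DAILY_FIXED
        ]
    raise ValueError(f"unknown candidate-set context {context!r}")
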