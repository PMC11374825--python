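"""Synthetic climate series and pregnancy cohorts with a known effect surface.

The real linked registry (415k Western Australian pregnancies, 2000-2015)
is not public, so every downstream stage is exercised on simulated data
whose generating truth is stored losslessly:

* daily location-level UTCI series: annual sinusoid peaking in the Southern
  Hemisphere summer plus AR(1) day-to-day noise and a location offset;
* a pregnancy cohort: conception dates over a configurable window,
  gestational lengths 20-42 completed weeks (mass concentrated at 37-41),
  covariates with configurable prevalences, and mutually exclusive
  gestational-hypertension / preeclampsia labels drawn from logistic models
  whose exposure terms come from a configurable lag-response surface
  ``f(x, week)`` on the log-odds scale, summed over the weeks the subject
  is at risk;
* the truth (surfaces, intercepts, covariate effects, seeds) serialised for
  parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exposure import (
    WEEK_MIN,
    WEEK_MAX,
    DailyExposureSeries,
    build_weekly_matrix,
)

__all__ = [
    "ClimateConfig",
    "CohortConfig",
    "TrueEffectSurface",
    "NullSurface",
    "InvertedUSurface",
    "SplineInvertedUSurface",
    "GridSurface",
    "SyntheticCohort",
    "generate_daily_utci",
    "generate_cohort",
    "true_lag_or",
    "surface_from_dict",
    "default_gestational_length_dist",
    "default_diagnosis_week_dist",
]


# ---------------------------------------------------------------------------
# Climate


@dataclass(frozen=True)
class ClimateConfig:
    """Daily-climate generator settings.

    Defaults emulate the pooled exposure summaries of a mostly temperate
    Southern Hemisphere population with a small tropical-north fraction:
    weekly means averaging ~14.5 deg C with weekly SD near 5 deg C, annual
    peak in mid-January, lag-1 daily autocorrelation 0.6, and a skewed
    location mixture (``hot_fraction`` of locations offset upward by
    ``hot_offset_range`` deg C) that reproduces a subject-average exposure
    distribution with a long right tail (99th centile near 26 deg C against
    a median near 14 deg C).
    """

    n_locations: int = 25
    date_start: str = "1998-06-01"
    date_end: str = "2016-12-31"
    mean_level: float = 14.5
    seasonal_amplitude: float = 6.0
    seasonal_phase: float = 15.0  # day-of-year of the annual maximum
    ar_coefficient: float = 0.6
    daily_noise_sd: float = 3.5
    location_offset_sd: float = 2.0
    hot_fraction: float = 0.08
    hot_offset_range: tuple[float, float] = (3.0, 13.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ValueError("n_locations must be positive")
        if np.datetime64(self.date_end) <= np.datetime64(self.date_start):
            raise ValueError("date_end must be after date_start")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.daily_noise_sd < 0 or self.location_offset_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.hot_fraction < 1:
            raise ValueError("hot_fraction must be in [0, 1)")


def generate_daily_utci(config: ClimateConfig) -> dict[str, DailyExposureSeries]:
    """Simulate one daily UTCI series per location.

    value(day) = mean_level + location offset
               + amplitude * cos(2*pi*(doy - phase)/365.25)
               + AR(1) noise (innovation SD ``daily_noise_sd``, initialised
                 at the stationary distribution)

    Deterministic in (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    start = np.datetime64(config.date_start, "D")
    end = np.datetime64(config.date_end, "D")
    n_days = int((end - start) / np.timedelta64(1, "D")) + 1
    dates = start + np.arange(n_days).astype("timedelta64[D]")
    doy = (dates - dates.astype("datetime64[Y]")).astype(int) + 1
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_phase) / 365.25
    )
    out = {}
    rho = config.ar_coefficient
    stat_sd = (
        config.daily_noise_sd / np.sqrt(1 - rho**2) if config.daily_noise_sd > 0 else 0.0
    )
    for i in range(config.n_locations):
        offset = rng.normal(0.0, config.location_offset_sd) if config.location_offset_sd else 0.0
        if config.hot_fraction and rng.random() < config.hot_fraction:
            offset += rng.uniform(*config.hot_offset_range)
        innov = rng.normal(0.0, config.daily_noise_sd, n_days) if config.daily_noise_sd else np.zeros(n_days)
        resid = np.empty(n_days)
        resid[0] = rng.normal(0.0, stat_sd) if stat_sd else 0.0
        for t in range(1, n_days):
            resid[t] = rho * resid[t - 1] + innov[t]
        loc = f"loc{i:03d}"
        out[loc] = DailyExposureSeries(
            location_id=loc,
            start_date=start,
            values=config.mean_level + offset + seasonal + resid,
        )
    return out


# ---------------------------------------------------------------------------
# Effect surfaces


class TrueEffectSurface:
    """Lag-response surface on the log-odds scale.

    ``f(x, week)`` gives the log-odds contribution of mean exposure ``x``
    (deg C) in week ``week`` (-11..42 relative to conception), centred so
    ``f(x_ref, week) = 0`` for every week.
    """

    tag: str = "abstract"
    x_ref: float = 14.2

    def f(self, x, week):  # pragma: no cover - abstract
        raise NotImplementedError

    def to_dict(self) -> dict:
        d = {"tag": self.tag}
        d.update({k: v for k, v in vars(self).items()})
        return d


class NullSurface(TrueEffectSurface):
    """No exposure effect at any lag."""

    tag = "null"

    def __init__(self, x_ref: float = 14.2):
        self.x_ref = float(x_ref)

    def f(self, x, week):
        return np.zeros(np.broadcast(np.asarray(x), np.asarray(week)).shape)


class InvertedUSurface(TrueEffectSurface):
    """Smooth inverted-U lag profile times a linear exposure ramp.

    ``f(x, w) = peak_log_or * (x - x_ref)/(x_high - x_ref)
                * exp(-(w - peak_week)^2 / (2 width^2))``

    so the log-OR at the high prediction level peaks at ``peak_log_or`` in
    ``peak_week`` and decays smoothly; the default width places the
    strongest effects in gestational weeks ~8-18 around a peak at week 13,
    with negligible contribution in the preconception weeks.  The default
    high level (26 deg C, a 99th-centile weekly exposure) carries a peak
    weekly OR of exp(0.1) ~ 1.10.
    """

    tag = "inverted_U"

    def __init__(
        self,
        x_ref: float = 14.2,
        x_high: float = 26.0,
        peak_log_or: float = 0.1,
        peak_week: float = 13.0,
        width: float = 5.5,
    ):
        self.x_ref = float(x_ref)
        self.x_high = float(x_high)
        self.peak_log_or = float(peak_log_or)
        self.peak_week = float(peak_week)
        self.width = float(width)

    def f(self, x, week):
        x = np.asarray(x, dtype=float)
        w = np.asarray(week, dtype=float)
        ramp = (x - self.x_ref) / (self.x_high - self.x_ref)
        bump = np.exp(-((w - self.peak_week) ** 2) / (2 * self.width**2))
        return self.peak_log_or * ramp * bump


class SplineInvertedUSurface(TrueEffectSurface):
    """Inverted-U surface whose lag profile lies in a natural-spline span.

    The target lag profile is a raised-cosine bump peaking at ``peak_week``
    with compact support ``peak_week +- half_width`` (zero by gestational
    week ~20, before the earliest possible diagnosis, so exposure after
    diagnosis is essentially inert).  That bump is projected onto the span
    (including constants) of the natural cubic spline basis on the integer
    week grid with ``lag_df`` columns and quantile knots, then rescaled so
    its grid maximum equals ``peak_log_or``; at coarse ``lag_df`` the
    projection smears a small remainder across neighbouring weeks while
    keeping the effect concentrated in early-to-mid pregnancy.  A DLNM
    whose lag basis uses the same (deterministic) knot rule can represent
    this surface exactly, so recovery experiments against it measure
    estimation error rather than spline approximation error.
    """

    tag = "inverted_U_spline"

    def __init__(
        self,
        x_ref: float = 14.2,
        x_high: float = 26.0,
        peak_log_or: float = 0.1,
        peak_week: float = 13.0,
        half_width: float = 7.0,
        lag_df: int = 6,
        week_min: int = WEEK_MIN,
        week_max: int = WEEK_MAX,
    ):
        from .basis import SplineSpec, natural_spline_basis

        self.x_ref = float(x_ref)
        self.x_high = float(x_high)
        self.peak_log_or = float(peak_log_or)
        self.peak_week = float(peak_week)
        self.half_width = float(half_width)
        self.lag_df = int(lag_df)
        self.week_min = int(week_min)
        self.week_max = int(week_max)
        grid = np.arange(week_min, week_max + 1, dtype=float)
        spec = SplineSpec.from_values(grid, df=lag_df, intercept=True)
        M = np.column_stack([np.ones_like(grid), natural_spline_basis(grid, spec)])
        u = np.clip(np.abs(grid - self.peak_week) / self.half_width, 0.0, 1.0)
        target = np.cos(np.pi * u / 2) ** 2
        coef, *_ = np.linalg.lstsq(M, target, rcond=None)
        scale = self.peak_log_or / np.max(M @ coef)
        self._lag_spec = spec
        self._coef = coef * scale

    def _bump(self, week):
        from .basis import natural_spline_basis

        w = np.asarray(week, dtype=float)
        M = np.column_stack([np.ones(w.size), natural_spline_basis(w.ravel(), self._lag_spec)])
        return (M @ self._coef).reshape(w.shape)

    def f(self, x, week):
        x = np.asarray(x, dtype=float)
        w = np.asarray(week, dtype=float)
        ramp = (x - self.x_ref) / (self.x_high - self.x_ref)
        return ramp * self._bump(w)

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "x_ref": self.x_ref,
            "x_high": self.x_high,
            "peak_log_or": self.peak_log_or,
            "peak_week": self.peak_week,
            "half_width": self.half_width,
            "lag_df": self.lag_df,
            "week_min": self.week_min,
            "week_max": self.week_max,
        }


class GridSurface(TrueEffectSurface):
    """Surface defined by bilinear interpolation of a (x, week) grid."""

    tag = "custom_grid"

    def __init__(self, x_grid, week_grid, values, x_ref: float):
        self.x_grid = np.asarray(x_grid, dtype=float)
        self.week_grid = np.asarray(week_grid, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.x_ref = float(x_ref)
        if self.values.shape != (self.x_grid.size, self.week_grid.size):
            raise ValueError("grid values must be (len(x_grid), len(week_grid))")

    def f(self, x, week):
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.x_grid, self.week_grid), self.values,
            bounds_error=False, fill_value=None,
        )
        x = np.asarray(x, dtype=float)
        w = np.asarray(week, dtype=float)
        xb, wb = np.broadcast_arrays(x, w)
        pts = np.column_stack([xb.ravel(), wb.ravel()])
        raw = interp(pts).reshape(xb.shape)
        ref = interp(np.column_stack([np.full(wb.ravel().shape, self.x_ref), wb.ravel()]))
        return raw - ref.reshape(wb.shape)

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "x_grid": self.x_grid.tolist(),
            "week_grid": self.week_grid.tolist(),
            "values": self.values.tolist(),
            "x_ref": self.x_ref,
        }


def surface_from_dict(d: Mapping) -> TrueEffectSurface:
    tag = d["tag"]
    params = {k: v for k, v in d.items() if k != "tag"}
    if tag == "null":
        return NullSurface(x_ref=params.get("x_ref", 14.2))
    if tag == "inverted_U":
        return InvertedUSurface(**params)
    if tag == "inverted_U_spline":
        return SplineInvertedUSurface(**params)
    if tag == "custom_grid":
        return GridSurface(**params)
    raise ValueError(f"unknown surface tag {tag!r}")


def true_lag_or(surface: TrueEffectSurface, x: float, weeks: Sequence[int]) -> np.ndarray:
    """Per-week true odds ratios at exposure ``x`` versus the surface's
    reference: ``OR_w = exp(f(x, w))``."""
    if not np.isfinite(x):
        raise ValueError("x must be finite")
    w = np.asarray(weeks)
    return np.exp(surface.f(np.full(w.shape, float(x)), w))


# ---------------------------------------------------------------------------
# Cohort


def default_gestational_length_dist() -> dict[int, float]:
    """Gestational-length distribution (completed weeks): ~90% mass on
    37-41, small early-delivery and post-term tails so onset strata are
    populated."""
    probs = {}
    early = np.linspace(1.0, 3.0, 17)  # weeks 20..36, rising toward term
    early = 0.08 * early / early.sum()
    for w, p in zip(range(20, 37), early):
        probs[w] = float(p)
    for w, p in zip(range(37, 42), [0.10, 0.17, 0.28, 0.25, 0.10]):
        probs[w] = p
    probs[42] = 0.02
    total = sum(probs.values())
    return {w: p / total for w, p in probs.items()}


def default_diagnosis_week_dist(early_fraction: float = 0.1) -> dict[int, float]:
    """Base diagnosis-week distribution for cases (before truncation at the
    subject's gestational length): ``early_fraction`` mass spread over weeks
    20-34, the rest peaked over 35-41."""
    probs = {w: early_fraction / 15 for w in range(20, 35)}
    late = np.array([0.10, 0.15, 0.20, 0.20, 0.16, 0.12, 0.05, 0.02])
    late = (1 - early_fraction) * late / late.sum()
    for w, p in zip(range(35, 43), late):
        probs[w] = float(p)
    return probs


def _default_covariate_prevalences() -> dict:
    return {
        "infant_sex": {"male": 0.512, "female": 0.488},
        "race": {"Caucasian": 0.783, "non-Caucasian": 0.217},
        "marital": {"married": 0.873, "unmarried": 0.127},
        "smoking": {"smoker": 0.147, "non-smoker": 0.853},
        "parity": {"nulliparous": 0.419, "multiparous": 0.581},
        "remoteness": {"urban": 0.619, "non-urban": 0.381},
        "ses": {"high": 1 / 3, "moderate": 1 / 3, "low": 1 / 3},
    }


@dataclass
class CohortConfig:
    """Pregnancy-cohort generator settings.

    ``alpha`` holds the per-outcome baseline log-odds; with null surfaces
    and zero covariate effects the outcome prevalence converges to
    ``expit(alpha)``.  Defaults match prevalences near 3.7% (gestational
    hypertension) and 2.8% (preeclampsia) with a late-onset preponderance.
    """

    n_pregnancies: int = 10_000
    conception_start: str = "1999-06-01"
    conception_end: str = "2015-03-01"
    gestational_length_dist: dict = field(default_factory=default_gestational_length_dist)
    alpha: dict = field(
        default_factory=lambda: {
            "gestational_hypertension": float(logit(0.037)),
            "preeclampsia": float(logit(0.028)),
        }
    )
    covariate_prevalences: dict = field(default_factory=_default_covariate_prevalences)
    covariate_effects: dict = field(default_factory=dict)  # e.g. {"smoking=smoker": -0.2}
    diagnosis_week_dist: dict = field(
        default_factory=lambda: {
            "gestational_hypertension": default_diagnosis_week_dist(0.075),
            "preeclampsia": default_diagnosis_week_dist(0.23),
        }
    )
    maternal_age_mean: float = 29.5
    maternal_age_sd: float = 5.5
    confounded_by_season: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pregnancies < 1:
            raise ValueError("n_pregnancies must be positive")
        if np.datetime64(self.conception_end) < np.datetime64(self.conception_start):
            raise ValueError("empty conception window")
        for name, dist in [("gestational_length", self.gestational_length_dist)] + [
            (f"diagnosis_week[{k}]", v) for k, v in self.diagnosis_week_dist.items()
        ]:
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(f"{name} distribution sums to {tot}, expected 1")
        if not set(self.gestational_length_dist) <= set(range(20, 43)):
            raise ValueError("gestational lengths must lie in 20..42")


@dataclass
class SyntheticCohort:
    """Generated records plus the lossless generating truth."""

    records: pd.DataFrame
    surfaces: dict  # outcome -> TrueEffectSurface
    config: CohortConfig
    climate_config: ClimateConfig | None = None
    weekly: object | None = None  # WeeklyExposureMatrix computed during generation

    def truth_dict(self) -> dict:
        return {
            "surfaces": {k: s.to_dict() for k, s in self.surfaces.items()},
            "alpha": self.config.alpha,
            "covariate_effects": self.config.covariate_effects,
            "seed": self.config.seed,
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=1, default=float)


def _sample_categorical(rng, levels, probs, n):
    return rng.choice(levels, size=n, p=probs)


def generate_cohort(
    cconf: CohortConfig,
    climate: Mapping[str, DailyExposureSeries],
    surfaces: Mapping[str, TrueEffectSurface] | TrueEffectSurface,
    climate_config: ClimateConfig | None = None,
) -> SyntheticCohort:
    """Simulate a pregnancy cohort against a climate panel.

    Outcomes are drawn from mutually exclusive Bernoulli draws with
    ``P(outcome o) = expit(alpha_o + sum_w f_o(x_w, w) + covariate terms)``
    where the lag sum runs over the weeks the subject is at risk (week -11
    through the gestational length).  Cases then receive a diagnosis week
    from the configured distribution truncated at the gestational length.
    """
    if isinstance(surfaces, TrueEffectSurface):
        surfaces = {"gestational_hypertension": surfaces}
    rng = np.random.default_rng(cconf.seed)
    n = cconf.n_pregnancies
    locs = sorted(climate.keys())

    start = np.datetime64(cconf.conception_start, "D")
    end = np.datetime64(cconf.conception_end, "D")
    span = int((end - start) / np.timedelta64(1, "D")) + 1
    conception = start + rng.integers(0, span, n).astype("timedelta64[D]")

    gl_weeks = np.array(sorted(cconf.gestational_length_dist))
    gl_probs = np.array([cconf.gestational_length_dist[w] for w in gl_weeks])
    gest_len = rng.choice(gl_weeks, size=n, p=gl_probs)

    location = rng.choice(locs, size=n)
    cov_cols = {}
    for name, prev in cconf.covariate_prevalences.items():
        levels = list(prev)
        probs = np.array([prev[v] for v in levels], dtype=float)
        probs = probs / probs.sum()
        cov_cols[name] = _sample_categorical(rng, levels, probs, n)
    age = np.clip(rng.normal(cconf.maternal_age_mean, cconf.maternal_age_sd, n), 15.0, 45.0)
    cov_cols["maternal_age"] = np.round(age, 1)

    months = pd.DatetimeIndex(conception.astype("datetime64[s]")).month.to_numpy()
    years = pd.DatetimeIndex(conception.astype("datetime64[s]")).year.to_numpy()
    if cconf.confounded_by_season:
        # Tie smoking prevalence to conception month so exposure and a
        # covariate share a seasonal cause, exercising adjustment.
        p_smoke = 0.10 + 0.10 * (np.cos(2 * np.pi * (months - 1) / 12) + 1) / 2
        cov_cols["smoking"] = np.where(rng.random(n) < p_smoke, "smoker", "non-smoker")

    cohort = pd.DataFrame(
        {
            "id": [f"p{i:06d}" for i in range(n)],
            "location_id": location,
            "conception_date": conception.astype("datetime64[s]"),
            "gestational_length": gest_len,
            "outcome": "none",
            "diagnosis_week": np.nan,
            **cov_cols,
            "conception_year": years,
            "conception_month": months,
        }
    )

    # Weekly exposures over the full at-risk range for the lag sums.
    weekly = build_weekly_matrix(climate, cohort, max_week=WEEK_MAX, padding="median")
    at_risk = weekly.weeks[None, :] <= np.minimum(gest_len, WEEK_MAX)[:, None]

    cov_term = np.zeros(n)
    for key, beta in cconf.covariate_effects.items():
        if "=" in key:
            name, level = key.split("=", 1)
            cov_term += beta * (cov_cols[name] == level)
        elif key == "maternal_age":
            cov_term += beta * (cov_cols["maternal_age"] - cconf.maternal_age_mean)
        else:
            raise ValueError(f"unrecognised covariate effect key {key!r}")

    wgrid = weekly.weeks.astype(float)
    p = {}
    for outcome, surf in surfaces.items():
        contrib = surf.f(weekly.values, wgrid[None, :])
        lag_sum = np.where(at_risk, contrib, 0.0).sum(axis=1)
        p[outcome] = expit(cconf.alpha[outcome] + lag_sum + cov_term)

    u = rng.random(n)
    lower = np.zeros(n)
    for outcome in p:  # mutually exclusive labels; sum of p stays << 1 here
        hit = (u >= lower) & (u < lower + p[outcome])
        cohort.loc[hit, "outcome"] = outcome
        lower = lower + p[outcome]

    # Diagnosis weeks for cases, truncated at the gestational length.
    for outcome, base in cconf.diagnosis_week_dist.items():
        idx = cohort.index[cohort["outcome"] == outcome]
        if len(idx) == 0:
            continue
        weeks = np.array(sorted(base))
        base_p = np.array([base[w] for w in weeks], dtype=float)
        g = cohort.loc[idx, "gestational_length"].to_numpy()
        uu = rng.random(len(idx))
        diag = np.empty(len(idx), dtype=int)
        for j, (gj, uj) in enumerate(zip(g, uu)):
            ok = weeks <= gj
            pj = base_p[ok] / base_p[ok].sum()
            diag[j] = int(weeks[ok][np.searchsorted(np.cumsum(pj), uj, side="right")])
        cohort.loc[idx, "diagnosis_week"] = diag

    return SyntheticCohort(
        records=cohort,
        surfaces=dict(surfaces),
        config=cconf,
        climate_config=climate_config,
        weekly=weekly,
    )
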