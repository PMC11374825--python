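"""Pregnancy-aligned exposure assembly from daily climate series.

Converts daily location-level UTCI values and pregnancy dates into the
weekly exposure histories and period averages used by the models:

* weekly means over the 7-day blocks of gestational weeks 1..42 and the 12
  preconception weeks -11..0 (week ``w`` covers days ``conception + 7(w-1)``
  through ``conception + 7w - 1``; week 0 is the 7 days immediately before
  conception);
* period averages (preconception-through-event, preconception, pregnancy,
  trimesters 1-3) over exact day ranges ending at the event day — the last
  day of the diagnosis week for cases, of the delivery week for controls;
* the fixed-cohort-bias filter restricting conception dates so every
  gestational length 20-42 weeks would deliver inside the observation
  window;
* exposure centile sets used as odds-ratio prediction levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DailyExposureSeries",
    "PregnancyRecord",
    "WeeklyExposureMatrix",
    "PeriodAverages",
    "CentileSet",
    "WEEK_MIN",
    "WEEK_MAX",
    "OUTCOMES",
    "end_week",
    "weekly_means",
    "build_weekly_matrix",
    "period_averages",
    "build_period_table",
    "apply_fixed_cohort_filter",
    "exposure_centiles",
    "classify_thermal_stress",
    "read_climate_csv",
    "write_climate_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_weekly_matrix_csv",
    "read_weekly_matrix_csv",
]

WEEK_MIN = -11  # first preconception week (12 weeks before conception)
WEEK_MAX = 42  # last gestational week
PRECONCEPTION_DAYS = 84  # 12 weeks

OUTCOMES = ("none", "gestational_hypertension", "preeclampsia")

# UTCI assessment scale: "no thermal stress" band in degrees Celsius.
NO_STRESS_LO = 9.0
NO_STRESS_HI = 26.0


class CoverageError(ValueError):
    """A pregnancy's exposure window is not covered by the climate series."""


@dataclass
class DailyExposureSeries:
    """Calendar-dated daily UTCI values (deg C) for one location."""

    location_id: str
    start_date: np.datetime64  # day resolution
    values: np.ndarray  # one value per consecutive calendar day

    def __post_init__(self) -> None:
        self.start_date = np.datetime64(self.start_date, "D")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("daily series contains non-finite values")

    @property
    def n_days(self) -> int:
        return self.values.size

    @property
    def end_date(self) -> np.datetime64:
        return self.start_date + np.timedelta64(self.n_days - 1, "D")

    def day_index(self, date) -> int:
        return int((np.datetime64(date, "D") - self.start_date) / np.timedelta64(1, "D"))

    def slice_mean(self, first_day, last_day) -> float:
        """Mean over the inclusive calendar-day range."""
        i0, i1 = self.day_index(first_day), self.day_index(last_day)
        if i0 < 0 or i1 >= self.n_days:
            raise CoverageError(
                f"location {self.location_id}: series covers "
                f"{self.start_date}..{self.end_date}, requested {first_day}..{last_day}"
            )
        return float(self.values[i0 : i1 + 1].mean())


@dataclass
class PregnancyRecord:
    """One singleton pregnancy with dates, outcome, and covariates."""

    id: str
    location_id: str
    conception_date: np.datetime64
    gestational_length: int  # completed weeks, 20..42
    outcome: str = "none"
    diagnosis_week: int | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conception_date = np.datetime64(self.conception_date, "D")
        self.gestational_length = int(self.gestational_length)
        if not 20 <= self.gestational_length <= 42:
            raise ValueError(
                f"gestational_length must be 20..42 weeks, got {self.gestational_length}"
            )
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "none":
            if self.diagnosis_week is not None:
                raise ValueError("diagnosis_week must be absent for non-cases")
        else:
            if self.diagnosis_week is None:
                raise ValueError("cases need a diagnosis_week")
            self.diagnosis_week = int(self.diagnosis_week)
            if not 20 <= self.diagnosis_week <= self.gestational_length:
                raise ValueError(
                    "diagnosis_week must lie in 20..gestational_length, got "
                    f"{self.diagnosis_week} (length {self.gestational_length})"
                )
        age = self.covariates.get("maternal_age")
        if age is not None and age > 45:
            raise ValueError(f"maternal_age must be <= 45, got {age}")


def end_week(record: PregnancyRecord | Mapping, max_week: int = WEEK_MAX) -> int:
    """Last gestational week of follow-up: diagnosis week for cases,
    delivery week for controls, capped at ``max_week``."""
    if isinstance(record, PregnancyRecord):
        outcome, diag, length = record.outcome, record.diagnosis_week, record.gestational_length
    else:
        outcome = record["outcome"]
        diag = record.get("diagnosis_week")
        length = record["gestational_length"]
    if outcome != "none" and diag is not None and not (isinstance(diag, float) and np.isnan(diag)):
        e = int(diag)
    else:
        e = int(length)
    return min(e, max_week)


@dataclass
class WeeklyExposureMatrix:
    """Subjects x week-index matrix of 7-day mean exposures.

    ``observed_mask[i, l]`` is True iff week ``weeks[l]`` is at or before
    subject ``i``'s end week; later entries are filled per ``padding``:

    * ``"median"`` — cohort median of observed values (padded weeks sit at
      the reference level of centred predictions);
    * ``"locf"`` — last observed week carried forward;
    * ``"natural"`` — the location's actual climate after the event, which
      keeps the design free of follow-up-length information (the padded
      count itself predicts case status when diagnosis ends follow-up, and
      any constant fill lets the model exploit that).

    The mask is always a prefix.
    """

    subject_ids: np.ndarray
    weeks: np.ndarray  # integer week indices, ordered
    values: np.ndarray  # (n, L), padded
    observed_mask: np.ndarray  # (n, L) bool
    padding: str = "median"

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[1] != self.weeks.size:
            raise ValueError("week index length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def observed_values(self) -> np.ndarray:
        return self.values[self.observed_mask]


def weekly_means(
    series: DailyExposureSeries,
    record: PregnancyRecord,
    max_week: int = WEEK_MAX,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weekly mean exposures for one pregnancy.

    Returns ``(weeks, values, observed_mask)`` over the full index
    ``WEEK_MIN..max_week``; values beyond the end week are NaN (padding is
    applied cohort-wide by :func:`build_weekly_matrix`).
    """
    weeks = np.arange(WEEK_MIN, max_week + 1)
    e = end_week(record, max_week)
    first_day = record.conception_date + np.timedelta64(7 * (WEEK_MIN - 1), "D")
    last_day = record.conception_date + np.timedelta64(7 * e - 1, "D")
    i0 = series.day_index(first_day)
    i1 = series.day_index(last_day)
    if i0 < 0 or i1 >= series.n_days:
        raise CoverageError(
            f"subject {record.id}: climate for location {series.location_id} covers "
            f"{series.start_date}..{series.end_date} but days {first_day}..{last_day} "
            "are required"
        )
    n_obs = e - WEEK_MIN + 1
    block = series.values[i0 : i0 + 7 * n_obs].reshape(n_obs, 7)
    values = np.full(weeks.size, np.nan)
    values[:n_obs] = block.mean(axis=1)
    mask = weeks <= e
    return weeks, values, mask


def build_weekly_matrix(
    climate: Mapping[str, DailyExposureSeries],
    cohort: pd.DataFrame,
    max_week: int = WEEK_MAX,
    padding: str = "median",
) -> WeeklyExposureMatrix:
    """Vectorised weekly exposure matrix for a whole cohort.

    ``cohort`` needs columns ``id, location_id, conception_date,
    gestational_length, outcome, diagnosis_week``.
    """
    if padding not in ("median", "locf", "natural"):
        raise ValueError(f"unknown padding policy {padding!r}")
    weeks = np.arange(WEEK_MIN, max_week + 1)
    L = weeks.size
    n = len(cohort)
    values = np.full((n, L), np.nan)
    mask = np.zeros((n, L), dtype=bool)

    conception = cohort["conception_date"].to_numpy().astype("datetime64[D]")
    diag = cohort["diagnosis_week"].to_numpy() if "diagnosis_week" in cohort else np.full(n, np.nan)
    is_case = (cohort["outcome"].to_numpy() != "none") & ~pd.isna(diag)
    ends = np.where(is_case, np.nan_to_num(pd.to_numeric(pd.Series(diag)), nan=0),
                    cohort["gestational_length"].to_numpy()).astype(int)
    ends = np.minimum(ends, max_week)

    # Per-location prefix sums: week mean = (S[i+7] - S[i]) / 7.
    for loc, sub in cohort.groupby("location_id", sort=False):
        if loc not in climate:
            raise CoverageError(f"no climate series for location {loc!r}")
        series = climate[loc]
        idx = sub.index
        pos = cohort.index.get_indexer(idx)
        S = np.concatenate(([0.0], np.cumsum(series.values)))
        first = ((conception[pos] - series.start_date) / np.timedelta64(1, "D")).astype(int) + 7 * (
            WEEK_MIN - 1
        )
        e = ends[pos]
        last = ((conception[pos] - series.start_date) / np.timedelta64(1, "D")).astype(int) + 7 * e - 1
        bad = (first < 0) | (last >= series.n_days)
        if np.any(bad):
            j = int(np.argmax(bad))
            d0 = series.start_date + np.timedelta64(int(first[j]), "D")
            d1 = series.start_date + np.timedelta64(int(last[j]), "D")
            raise CoverageError(
                f"subject {cohort.iloc[pos[j]]['id']}: climate for location "
                f"{loc} covers {series.start_date}..{series.end_date} but days "
                f"{d0}..{d1} are required"
            )
        # start index of each week block for each subject: first + 7*t
        t = np.arange(L)
        starts = first[:, None] + 7 * t[None, :]
        valid = (starts >= 0) & (starts + 7 <= series.n_days)
        if padding == "natural" and not valid.all():
            raise CoverageError(
                f"natural padding needs climate for location {loc} through "
                f"week {max_week} of every pregnancy; series ends {series.end_date}"
            )
        starts_c = np.clip(starts, 0, max(series.n_days - 7, 0))
        wk = (S[starts_c + 7] - S[starts_c]) / 7.0
        obs = weeks[None, :] <= e[:, None]
        if padding != "natural":
            wk[~obs] = np.nan
        values[pos] = wk
        mask[pos] = obs

    if padding == "natural":
        pass  # post-event weeks already hold the location's real climate
    elif padding == "median":
        fill = float(np.nanmedian(values[mask])) if mask.any() else 0.0
        values[~mask] = fill
    else:  # locf
        for i in range(n):
            e = ends[i]
            k = e - WEEK_MIN
            values[i, k + 1 :] = values[i, k]
    return WeeklyExposureMatrix(
        subject_ids=cohort["id"].to_numpy(),
        weeks=weeks,
        values=values,
        observed_mask=mask,
        padding=padding,
    )


@dataclass
class PeriodAverages:
    """Daily-mean exposure over the study's summary periods (deg C).

    Fields are NaN when the subject's follow-up ends before the period
    starts.
    """

    preconception_through_event: float
    preconception: float
    pregnancy: float
    trimester1: float
    trimester2: float
    trimester3: float


def _day_range_mean(series: DailyExposureSeries, conception, off0: int, off1: int) -> float:
    first = conception + np.timedelta64(off0, "D")
    last = conception + np.timedelta64(off1, "D")
    return series.slice_mean(first, last)


def period_averages(series: DailyExposureSeries, record: PregnancyRecord) -> PeriodAverages:
    """Period-average exposures for one pregnancy.

    The event day is the last day of the diagnosis week (cases) or of the
    delivery week (controls): day offset ``7 * end_week - 1`` from
    conception.  Trimesters are weeks 1-13, 14-26 and 27-event; a trimester
    is absent (NaN) if follow-up ends before it starts and truncated at the
    event day otherwise.
    """
    c = record.conception_date
    e = end_week(record)
    event_off = 7 * e - 1
    out = {
        "preconception_through_event": _day_range_mean(series, c, -PRECONCEPTION_DAYS, event_off),
        "preconception": _day_range_mean(series, c, -PRECONCEPTION_DAYS, -1),
        "pregnancy": _day_range_mean(series, c, 0, event_off),
        "trimester1": _day_range_mean(series, c, 0, min(event_off, 7 * 13 - 1)),
        "trimester2": (
            _day_range_mean(series, c, 7 * 13, min(event_off, 7 * 26 - 1)) if e >= 14 else np.nan
        ),
        "trimester3": (_day_range_mean(series, c, 7 * 26, event_off) if e >= 27 else np.nan),
    }
    return PeriodAverages(**out)


def build_period_table(
    climate: Mapping[str, DailyExposureSeries], cohort: pd.DataFrame
) -> pd.DataFrame:
    """Period averages for a whole cohort, indexed like ``cohort``."""
    rows = []
    for _, r in cohort.iterrows():
        rec = PregnancyRecord(
            id=str(r["id"]),
            location_id=r["location_id"],
            conception_date=r["conception_date"],
            gestational_length=r["gestational_length"],
            outcome=r["outcome"],
            diagnosis_week=None
            if r["outcome"] == "none" or pd.isna(r.get("diagnosis_week"))
            else int(r["diagnosis_week"]),
        )
        pa = period_averages(climate[r["location_id"]], rec)
        rows.append(vars(pa))
    return pd.DataFrame(rows, index=cohort.index)


def build_period_table_fast(
    weekly: WeeklyExposureMatrix, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Week-resolution period averages from an assembled weekly matrix.

    Exact when each period spans whole weeks (always true here: periods
    start and end on week boundaries and the event day closes a week).
    """
    w = weekly.weeks
    V = np.where(weekly.observed_mask, weekly.values, np.nan)

    def mean_over(lo, hi):
        cols = (w >= lo) & (w <= hi)
        sub = V[:, cols]
        cnt = np.isfinite(sub).sum(axis=1)
        tot = np.nansum(sub, axis=1)
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    ends = np.array([end_week(r) for _, r in cohort.iterrows()])
    out = pd.DataFrame(
        {
            "preconception_through_event": mean_over(WEEK_MIN, WEEK_MAX),
            "preconception": mean_over(WEEK_MIN, 0),
            "pregnancy": mean_over(1, WEEK_MAX),
            "trimester1": mean_over(1, 13),
            "trimester2": mean_over(14, 26),
            "trimester3": mean_over(27, WEEK_MAX),
        },
        index=cohort.index,
    )
    out.loc[ends < 14, "trimester2"] = np.nan
    out.loc[ends < 27, "trimester3"] = np.nan
    return out


def apply_fixed_cohort_filter(
    cohort: pd.DataFrame, cohort_start, cohort_end
) -> tuple[pd.DataFrame, dict]:
    """Remove fixed cohort bias: keep conceptions for which every
    gestational length 20-42 weeks would deliver inside the window.

    Retains rows with ``cohort_start - 20 weeks <= conception_date <=
    cohort_end - 42 weeks``.  Returns the filtered frame and exclusion
    counts.
    """
    start = np.datetime64(cohort_start, "D")
    end = np.datetime64(cohort_end, "D")
    lo = start - np.timedelta64(140, "D")  # 20 weeks
    hi = end - np.timedelta64(294, "D")  # 42 weeks
    if hi < lo:
        raise ValueError(
            f"empty eligibility window: cohort_end - 42w ({hi}) precedes "
            f"cohort_start - 20w ({lo})"
        )
    if len(cohort) == 0:
        return cohort.copy(), {"retained": 0, "excluded_early": 0, "excluded_late": 0}
    conc = cohort["conception_date"].to_numpy().astype("datetime64[D]")
    keep = (conc >= lo) & (conc <= hi)
    counts = {
        "retained": int(keep.sum()),
        "excluded_early": int((conc < lo).sum()),
        "excluded_late": int((conc > hi).sum()),
    }
    return cohort.loc[keep].copy(), counts


@dataclass
class CentileSet:
    """Exposure prediction levels (deg C) for odds-ratio curves."""

    p1: float
    p5: float
    median: float
    mean: float
    p95: float
    p99: float
    source: str = ""

    def __post_init__(self) -> None:
        q = [self.p1, self.p5, self.median, self.p95, self.p99]
        if not all(a <= b + 1e-12 for a, b in zip(q, q[1:])):
            raise ValueError(f"centiles must be non-decreasing, got {q}")

    def levels(self) -> dict[str, float]:
        return {"P1": self.p1, "P5": self.p5, "P95": self.p95, "P99": self.p99}

    def to_dict(self) -> dict:
        return vars(self).copy()


def exposure_centiles(values: Iterable[float], source: str = "") -> CentileSet:
    """Centile set by linear interpolation between order statistics."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("cannot compute centiles of an empty collection")
    p1, p5, med, p95, p99 = np.quantile(x, [0.01, 0.05, 0.5, 0.95, 0.99])
    return CentileSet(
        p1=float(p1), p5=float(p5), median=float(med), mean=float(x.mean()),
        p95=float(p95), p99=float(p99), source=source,
    )


def classify_thermal_stress(x):
    """UTCI assessment category: cold stress below 9 deg C, heat stress
    above 26 deg C, otherwise no thermal stress."""
    arr = np.asarray(x, dtype=float)
    out = np.where(arr < NO_STRESS_LO, "cold stress",
                   np.where(arr > NO_STRESS_HI, "heat stress", "no thermal stress"))
    return out.item() if np.isscalar(x) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV interfaces


def write_climate_csv(climate: Mapping[str, DailyExposureSeries], path) -> None:
    frames = []
    for loc, s in climate.items():
        dates = s.start_date + np.arange(s.n_days).astype("timedelta64[D]")
        frames.append(
            pd.DataFrame({"location_id": loc, "date": dates, "utci_celsius": s.values})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, date_format="%Y-%m-%d")


def read_climate_csv(path) -> dict[str, DailyExposureSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for loc, sub in df.groupby("location_id", sort=False):
        sub = sub.sort_values("date")
        dates = sub["date"].to_numpy().astype("datetime64[D]")
        gaps = np.diff(dates) != np.timedelta64(1, "D")
        if np.any(gaps):
            first = dates[:-1][gaps][0]
            raise ValueError(f"climate series {loc} has a date gap after {first}")
        out[str(loc)] = DailyExposureSeries(
            location_id=str(loc), start_date=dates[0], values=sub["utci_celsius"].to_numpy()
        )
    return out


COHORT_COLUMNS = [
    "id", "location_id", "conception_date", "gestational_length", "outcome",
    "diagnosis_week", "infant_sex", "maternal_age", "race", "marital", "smoking",
    "parity", "remoteness", "ses", "conception_year", "conception_month",
]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cohort.to_csv(path, index=False, columns=cols, date_format="%Y-%m-%d")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["conception_date"])
    df["conception_date"] = df["conception_date"].astype("datetime64[s]")
    return df


def _week_label(w: int) -> str:
    return f"w_m{-w}" if w < 0 else f"w_{w}"


def write_weekly_matrix_csv(weekly: WeeklyExposureMatrix, path) -> None:
    cols = [_week_label(int(w)) for w in weekly.weeks]
    df = pd.DataFrame(weekly.values, columns=cols)
    df.insert(0, "id", weekly.subject_ids)
    df["end_week"] = weekly.weeks[weekly.observed_mask.sum(axis=1) - 1]
    df["padding"] = weekly.padding
    df.to_csv(path, index=False)


def read_weekly_matrix_csv(path) -> WeeklyExposureMatrix:
    df = pd.read_csv(path)
    wcols = [c for c in df.columns if c.startswith("w_")]
    weeks = np.array([-int(c[3:]) if c.startswith("w_m") else int(c[2:]) for c in wcols])
    values = df[wcols].to_numpy(dtype=float)
    ends = df["end_week"].to_numpy()
    mask = weeks[None, :] <= ends[:, None]
    padding = str(df["padding"].iloc[0]) if len(df) else "median"
    return WeeklyExposureMatrix(
        subject_ids=df["id"].to_numpy(), weeks=weeks, values=values,
        observed_mask=mask, padding=padding,
    )
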