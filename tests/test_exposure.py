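"""Weekly exposure assembly, period averages, eligibility filter, centiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from utcidlnm.exposure import (
    WEEK_MIN,
    CentileSet,
    CoverageError,
    DailyExposureSeries,
    PregnancyRecord,
    apply_fixed_cohort_filter,
    build_period_table_fast,
    build_weekly_matrix,
    classify_thermal_stress,
    exposure_centiles,
    period_averages,
    read_weekly_matrix_csv,
    weekly_means,
    write_weekly_matrix_csv,
)
from tests.conftest import make_cohort_frame


def make_record(**kw):
    defaults = dict(
        id="r1", location_id="locX", conception_date="2000-02-01",
        gestational_length=40,
    )
    defaults.update(kw)
    return PregnancyRecord(**defaults)


class TestWeeklyMeans:
    def test_constant_series(self, constant_series):
        s = constant_series(14.0, start="1999-06-01")
        weeks, values, mask = weekly_means(s, make_record())
        assert np.all(values[mask] == 14.0)
        assert weeks[0] == WEEK_MIN and weeks[-1] == 42

    def test_single_week_arithmetic_mean(self, constant_series):
        s = constant_series(0.0, start="1999-06-01")
        # gestational week 1 covers the 7 days from conception
        c = np.datetime64("2000-02-01")
        i0 = s.day_index(c)
        s.values[i0 : i0 + 7] = [10, 11, 12, 13, 14, 15, 16]
        _, values, _ = weekly_means(s, make_record())
        w1 = np.flatnonzero(np.arange(WEEK_MIN, 43) == 1)[0]
        assert values[w1] == 13.0

    def test_leap_week_matches_date_oracle(self, constant_series):
        """A week straddling 28 Feb - 5 Mar 2000 (leap year) averages those
        exact 7 calendar days."""
        s = constant_series(0.0, start="1999-06-01")
        dates = s.start_date + np.arange(s.n_days).astype("timedelta64[D]")
        s.values[:] = np.arange(s.n_days, dtype=float)  # value == day index
        rec = make_record(conception_date="2000-02-28")
        _, values, _ = weekly_means(s, rec)
        w1 = np.flatnonzero(np.arange(WEEK_MIN, 43) == 1)[0]
        # independent oracle: enumerate the calendar days and average
        want_days = [np.datetime64("2000-02-28") + np.timedelta64(k, "D") for k in range(7)]
        oracle = np.mean([s.values[list(dates).index(d)] for d in want_days])
        assert values[w1] == oracle
        assert np.datetime64("2000-03-05") in want_days  # straddles Feb 29

    def test_preconception_week_zero_precedes_conception(self, constant_series):
        s = constant_series(0.0, start="1999-06-01")
        c = np.datetime64("2000-02-01")
        i0 = s.day_index(c)
        s.values[i0 - 7 : i0] = 5.0  # the 7 days immediately before conception
        _, values, _ = weekly_means(s, make_record())
        w0 = np.flatnonzero(np.arange(WEEK_MIN, 43) == 0)[0]
        assert values[w0] == 5.0

    def test_case_masked_after_diagnosis(self, constant_series):
        s = constant_series(14.0, start="1999-06-01")
        rec = make_record(outcome="preeclampsia", diagnosis_week=30)
        weeks, values, mask = weekly_means(s, rec)
        assert mask[weeks <= 30].all()
        assert not mask[weeks > 30].any()
        assert np.isnan(values[~mask]).all()

    def test_coverage_gap_raises_with_dates(self, constant_series):
        s = constant_series(14.0, start="2000-01-20")  # starts too late
        with pytest.raises(CoverageError, match="locX"):
            weekly_means(s, make_record())


class TestBuildWeeklyMatrix:
    def test_matches_single_subject_path(self, small_climate, small_cohort):
        cohort = small_cohort.records.head(25)
        wm = build_weekly_matrix(small_climate, cohort)
        for pos in [0, 7, 24]:
            r = cohort.iloc[pos]
            rec = PregnancyRecord(
                id=r["id"], location_id=r["location_id"],
                conception_date=r["conception_date"],
                gestational_length=r["gestational_length"],
                outcome=r["outcome"],
                diagnosis_week=None if pd.isna(r["diagnosis_week"]) else int(r["diagnosis_week"]),
            )
            _, values, mask = weekly_means(small_climate[r["location_id"]], rec)
            assert np.array_equal(wm.observed_mask[pos], mask)
            assert np.allclose(wm.values[pos][mask], values[mask])

    def test_mask_is_prefix(self, small_climate, small_cohort):
        wm = build_weekly_matrix(small_climate, small_cohort.records)
        flipped = np.diff(wm.observed_mask.astype(int), axis=1)
        assert (flipped <= 0).all()  # once unobserved, never observed again

    @pytest.mark.parametrize("padding", ["median", "locf", "natural"])
    def test_padding_policies_fill_everything(self, small_climate, small_cohort, padding):
        wm = build_weekly_matrix(small_climate, small_cohort.records, padding=padding)
        assert np.all(np.isfinite(wm.values))
        if padding == "median":
            fill = np.median(wm.values[wm.observed_mask])
            assert np.allclose(wm.values[~wm.observed_mask], fill)

    def test_csv_round_trip(self, small_climate, small_cohort, tmp_path):
        wm = build_weekly_matrix(small_climate, small_cohort.records.head(50))
        p = tmp_path / "weekly.csv"
        write_weekly_matrix_csv(wm, p)
        wm2 = read_weekly_matrix_csv(p)
        assert np.array_equal(wm.weeks, wm2.weeks)
        assert np.array_equal(wm.observed_mask, wm2.observed_mask)
        assert np.allclose(wm.values, wm2.values)

    def test_row_sum_identity(self, constant_series):
        """The pregnancy-period average equals the day-weighted mean of the
        observed pregnancy weekly means (exact: follow-up is whole weeks)."""
        s = constant_series(0.0, start="1999-06-01", n_days=1200)
        s.values[:] = np.sin(np.arange(s.n_days) / 13.0) * 8 + 14
        rec = make_record(gestational_length=38)
        weeks, values, mask = weekly_means(s, rec)
        preg = (weeks >= 1) & mask
        weekly_mean = values[preg].mean()
        pa = period_averages(s, rec)
        assert np.isclose(pa.pregnancy, weekly_mean, atol=1e-12)


class TestPeriodAverages:
    def test_constant_series_every_period(self, constant_series):
        s = constant_series(16.5, start="1999-06-01")
        pa = period_averages(s, make_record())
        for name in ("preconception_through_event", "preconception", "pregnancy",
                     "trimester1", "trimester2", "trimester3"):
            assert getattr(pa, name) == 16.5

    def test_short_follow_up_truncates_trimesters(self, constant_series):
        """A 20-week control has no trimester 3; trimester 2 covers weeks
        14-20 only (checked against a brute-force day-range mean)."""
        s = constant_series(0.0, start="1999-06-01", n_days=1100)
        s.values[:] = np.arange(s.n_days, dtype=float)
        rec = make_record(gestational_length=20)
        pa = period_averages(s, rec)
        assert np.isnan(pa.trimester3)
        c = s.day_index(np.datetime64("2000-02-01"))
        oracle_t2 = s.values[c + 7 * 13 : c + 7 * 20].mean()  # weeks 14..20
        assert np.isclose(pa.trimester2, oracle_t2)

    def test_case_pregnancy_mean_covers_210_days(self, constant_series):
        s = constant_series(0.0, start="1999-06-01", n_days=1100)
        s.values[:] = np.arange(s.n_days, dtype=float)
        rec = make_record(outcome="gestational_hypertension", diagnosis_week=30)
        pa = period_averages(s, rec)
        c = s.day_index(np.datetime64("2000-02-01"))
        assert np.isclose(pa.pregnancy, s.values[c : c + 210].mean())

    def test_fast_table_matches_slow_path(self, small_climate, small_cohort):
        cohort = small_cohort.records.head(40)
        wm = build_weekly_matrix(small_climate, cohort)
        fast = build_period_table_fast(wm, cohort)
        for pos in [0, 13, 39]:
            r = cohort.iloc[pos]
            rec = PregnancyRecord(
                id=r["id"], location_id=r["location_id"],
                conception_date=r["conception_date"],
                gestational_length=r["gestational_length"],
                outcome=r["outcome"],
                diagnosis_week=None if pd.isna(r["diagnosis_week"]) else int(r["diagnosis_week"]),
            )
            pa = period_averages(small_climate[r["location_id"]], rec)
            for name in ("preconception", "pregnancy", "trimester1", "trimester2", "trimester3"):
                want = getattr(pa, name)
                got = fast.iloc[pos][name]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert np.isclose(got, want, atol=1e-9)


class TestFixedCohortFilter:
    START, END = "2000-01-01", "2015-12-31"

    def test_boundary_conceptions(self):
        lo = np.datetime64(self.START) - np.timedelta64(140, "D")
        hi = np.datetime64(self.END) - np.timedelta64(294, "D")
        df = make_cohort_frame(
            [
                {"conception_date": str(lo)},                      # exactly start - 20w
                {"conception_date": str(lo - np.timedelta64(1, "D"))},
                {"conception_date": str(hi)},                      # exactly end - 42w
                {"conception_date": str(np.datetime64(self.END) - np.timedelta64(287, "D"))},  # end - 41w
            ]
        )
        kept, counts = apply_fixed_cohort_filter(df, self.START, self.END)
        assert list(kept["id"]) == ["s0", "s2"]
        assert counts == {"retained": 2, "excluded_early": 1, "excluded_late": 1}

    def test_idempotent(self, small_cohort):
        kept1, _ = apply_fixed_cohort_filter(small_cohort.records, self.START, self.END)
        kept2, counts2 = apply_fixed_cohort_filter(kept1, self.START, self.END)
        pd.testing.assert_frame_equal(kept1, kept2)
        assert counts2["excluded_early"] == 0 and counts2["excluded_late"] == 0

    def test_empty_input(self):
        df = pd.DataFrame({"id": pd.Series(dtype=str),
                           "conception_date": pd.Series(dtype="datetime64[s]")})
        kept, counts = apply_fixed_cohort_filter(df, self.START, self.END)
        assert len(kept) == 0
        assert counts["retained"] == 0

    def test_inverted_window_raises(self):
        df = make_cohort_frame([{"conception_date": "2000-01-01"}])
        with pytest.raises(ValueError, match="empty eligibility window"):
            apply_fixed_cohort_filter(df, "2000-01-01", "2000-06-01")


class TestCentiles:
    def test_median_of_1_to_5(self):
        cs = exposure_centiles([1, 2, 3, 4, 5])
        assert cs.median == 3

    def test_linear_interpolation_oracle(self):
        """P1/P99 of 1..99 under the continuous order-statistic convention."""
        cs = exposure_centiles(np.arange(1, 100, dtype=float))
        assert np.isclose(cs.p1, 1.98)
        assert np.isclose(cs.p99, 98.02)

    def test_identical_values(self):
        cs = exposure_centiles(np.full(50, 7.5))
        assert cs.p1 == cs.p5 == cs.median == cs.p95 == cs.p99 == 7.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exposure_centiles([])

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            CentileSet(p1=5, p5=4, median=3, mean=3, p95=2, p99=1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=200))
    def test_monotone_on_any_input(self, values):
        cs = exposure_centiles(values)
        assert cs.p1 <= cs.p5 <= cs.median <= cs.p95 <= cs.p99


class TestThermalStress:
    @pytest.mark.parametrize(
        "x,want",
        [
            (15.0, "no thermal stress"),
            (9.0, "no thermal stress"),
            (26.0, "no thermal stress"),
            (8.9, "cold stress"),
            (26.1, "heat stress"),
            (-10.0, "cold stress"),
            (39.0, "heat stress"),
        ],
    )
    def test_boundaries(self, x, want):
        assert classify_thermal_stress(x) == want

    def test_vectorised(self):
        out = classify_thermal_stress(np.array([0.0, 15.0, 30.0]))
        assert list(out) == ["cold stress", "no thermal stress", "heat stress"]


class TestPregnancyRecordInvariants:
    def test_rejects_bad_gestational_length(self):
        with pytest.raises(ValueError):
            make_record(gestational_length=19)

    def test_rejects_diagnosis_after_delivery(self):
        with pytest.raises(ValueError):
            make_record(outcome="preeclampsia", diagnosis_week=41, gestational_length=40)

    def test_rejects_overage_mother(self):
        with pytest.raises(ValueError, match="maternal_age"):
            make_record(covariates={"maternal_age": 46})
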