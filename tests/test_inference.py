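"""Odds-ratio curves, cumulative ORs, delta-method CIs, critical windows."""

import numpy as np
import pytest

from utcidlnm.basis import build_cross_basis, natural_spline_basis
from utcidlnm.exposure import build_weekly_matrix
from utcidlnm.fit import assemble_design, fit_logistic
from utcidlnm.inference import (
    LagORCurve,
    Z95,
    cumulative_or,
    curve_to_frame,
    detect_critical_windows,
    lag_specific_or,
)

rng = np.random.default_rng(15)


@pytest.fixture(scope="module")
def fitted_dlnm(small_climate, small_cohort):
    wm = build_weekly_matrix(small_climate, small_cohort.records, padding="median")
    y = (small_cohort.records["outcome"] == "gestational_hypertension").to_numpy(float)
    cb = build_cross_basis(wm.values, wm.weeks, df_x=3, df_lag=3,
                           knot_values=wm.observed_values())
    names = [f"cb{j}" for j in range(cb.matrix.shape[1])]
    design = assemble_design(y, cb.matrix, names, block_name="crossbasis")
    fit = fit_logistic(design)
    fit.meta["crossbasis_hash"] = cb.hash()
    return fit, cb


class TestLagSpecificOR:
    def test_reference_level_gives_unit_or_zero_width(self, fitted_dlnm):
        fit, cb = fitted_dlnm
        curve = lag_specific_or(fit, cb, 14.2, 14.2)
        assert np.allclose(curve.or_, 1.0)
        assert np.allclose(curve.lo, 1.0) and np.allclose(curve.hi, 1.0)

    def test_ci_brackets_point_estimate(self, fitted_dlnm):
        fit, cb = fitted_dlnm
        curve = lag_specific_or(fit, cb, 20.0, 14.2)
        assert np.all(curve.lo <= curve.or_) and np.all(curve.or_ <= curve.hi)

    def test_reduction_to_plain_logistic(self, small_climate, small_cohort):
        """With a single linear exposure column and a constant lag basis the
        weekly OR is flat and equals exp(beta (x - x_ref)) from an ordinary
        logistic fit on the lag-summed exposure."""
        from utcidlnm.basis import CrossBasis, SplineSpec, cross_basis_from_marginals
        from utcidlnm.fit import ModelDesign

        wm = build_weekly_matrix(small_climate, small_cohort.records, padding="median")
        y = (small_cohort.records["outcome"] == "gestational_hypertension").to_numpy(float)
        n, L = wm.values.shape
        # plain logistic on the summed exposure
        s = wm.values.sum(axis=1)
        X = np.column_stack([np.ones(n), s])
        ref = fit_logistic(ModelDesign(y=y, X=X, column_names=["intercept", "s"], blocks={}))
        slope = ref.beta[1]
        # degenerate cross-basis: identity x-basis, all-ones lag basis
        M = cross_basis_from_marginals(wm.values[:, :, None], np.ones((L, 1)))
        design = assemble_design(y, M, ["cb0"], block_name="crossbasis")
        fit = fit_logistic(design)
        x, x_ref = 20.0, 14.2
        expected = np.exp(slope * (x - x_ref))
        # manual contrast: dBx = x - x_ref, Blag = 1 at every week
        d_eta = fit.coef("crossbasis")[0] * (x - x_ref)
        assert abs(fit.coef("crossbasis")[0] - slope) < 1e-8
        assert np.isclose(np.exp(d_eta), expected)

    def test_delta_method_matches_monte_carlo(self, fitted_dlnm):
        """Delta-method CI vs a parametric Monte-Carlo oracle: draw beta
        from N(beta_hat, V) and compare the log-OR quantiles."""
        fit, cb = fitted_dlnm
        x, x_ref = 20.0, 14.2
        curve = lag_specific_or(fit, cb, x, x_ref)
        B = natural_spline_basis(np.array([x, x_ref]), cb.x_spec)
        dBx = B[0] - B[1]
        Blag = natural_spline_basis(cb.lags.astype(float), cb.lag_spec)
        C = np.einsum("j,lk->ljk", dBx, Blag).reshape(cb.lags.size, -1)
        draws = rng.multivariate_normal(
            fit.coef("crossbasis"), fit.cov_block("crossbasis"), size=100_000
        )
        sim = draws @ C.T  # (100k, L)
        lo_mc = np.quantile(sim, 0.025, axis=0)
        hi_mc = np.quantile(sim, 0.975, axis=0)
        assert np.abs(np.log(curve.lo) - lo_mc).max() < 0.01
        assert np.abs(np.log(curve.hi) - hi_mc).max() < 0.01

    def test_extrapolation_flagged(self, fitted_dlnm):
        fit, cb = fitted_dlnm
        beyond = cb.x_spec.boundary_knots[1] + 5.0
        assert lag_specific_or(fit, cb, beyond, 14.2).extrapolated
        assert not lag_specific_or(fit, cb, 15.0, 14.2).extrapolated

    def test_hash_mismatch_rejected(self, fitted_dlnm, small_climate, small_cohort):
        fit, cb = fitted_dlnm
        wm = build_weekly_matrix(small_climate, small_cohort.records, padding="median")
        other = build_cross_basis(wm.values, wm.weeks, df_x=3, df_lag=3,
                                  knot_values=wm.observed_values()[:500])
        with pytest.raises(ValueError, match="hash"):
            lag_specific_or(fit, other, 20.0, 14.2)


class TestCumulativeOR:
    def test_singleton_week_equals_weekly_or(self, fitted_dlnm):
        fit, cb = fitted_dlnm
        curve = lag_specific_or(fit, cb, 20.0, 14.2)
        co = cumulative_or(fit, cb, 20.0, 14.2, weeks=[5])
        i = np.flatnonzero(curve.weeks == 5)[0]
        assert np.isclose(co.log_or, curve.log_or[i])
        assert np.isclose(co.se, curve.se[i])

    def test_log_cumulative_equals_sum_of_weekly(self, fitted_dlnm):
        fit, cb = fitted_dlnm
        for x in (10.0, 18.0, 25.0):
            curve = lag_specific_or(fit, cb, x, 14.2)
            co = cumulative_or(fit, cb, x, 14.2)
            assert abs(co.log_or - curve.log_or.sum()) < 1e-10

    def test_empty_week_set_rejected(self, fitted_dlnm):
        fit, cb = fitted_dlnm
        with pytest.raises(ValueError, match="empty week set"):
            cumulative_or(fit, cb, 20.0, 14.2, weeks=[])

    def test_contrast_symmetry(self, fitted_dlnm):
        """Swapping x and x_ref inverts the cumulative OR exactly."""
        fit, cb = fitted_dlnm
        a = cumulative_or(fit, cb, 20.0, 14.2)
        b = cumulative_or(fit, cb, 14.2, 20.0)
        assert np.isclose(a.log_or, -b.log_or)
        assert np.isclose(a.se, b.se)


def make_curve(weeks, log_or, se):
    return LagORCurve(weeks=np.asarray(weeks), x=20.0, x_ref=14.2,
                      log_or=np.asarray(log_or, float), se=np.asarray(se, float))


class TestCriticalWindows:
    def test_all_cis_cover_one_gives_empty(self):
        c = make_curve(np.arange(-11, 43), np.zeros(54), np.ones(54))
        assert detect_critical_windows(c) == []

    def test_single_harmful_run_8_to_18(self):
        weeks = np.arange(-11, 43)
        log_or = np.zeros(54)
        se = np.full(54, 0.05)
        sig = (weeks >= 8) & (weeks <= 18)
        log_or[sig] = 0.05 * Z95 + 0.01  # lower CI just above 1
        wins = detect_critical_windows(make_curve(weeks, log_or, se))
        assert len(wins) == 1
        w = wins[0]
        assert (w.start, w.end, w.direction) == (8, 18, "harmful")

    def test_min_run_drops_isolated_week(self):
        weeks = np.arange(0, 10)
        log_or = np.zeros(10)
        se = np.full(10, 0.05)
        log_or[4] = 1.0
        assert detect_critical_windows(make_curve(weeks, log_or, se), min_run=2) == []
        assert len(detect_critical_windows(make_curve(weeks, log_or, se), min_run=1)) == 1

    def test_directions_split_runs(self):
        weeks = np.arange(0, 6)
        log_or = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 1.0])
        se = np.full(6, 0.05)
        wins = detect_critical_windows(make_curve(weeks, log_or, se))
        assert [(w.start, w.end, w.direction) for w in wins] == [
            (0, 1, "harmful"), (2, 3, "protective"), (5, 5, "harmful"),
        ]


def test_reference_invariance_of_contrast(fitted_dlnm):
    """Adding a constant to both B_x(x) and B_x(x_ref) leaves the log-OR
    unchanged (the contrast depends only on the difference)."""
    fit, cb = fitted_dlnm
    x, x_ref = 22.0, 14.2
    B = natural_spline_basis(np.array([x, x_ref]), cb.x_spec)
    dBx = B[0] - B[1]
    shifted = (B[0] + 3.7) - (B[1] + 3.7)
    assert np.allclose(dBx, shifted)
    Blag = natural_spline_basis(cb.lags.astype(float), cb.lag_spec)
    C = np.einsum("j,lk->ljk", dBx, Blag).reshape(cb.lags.size, -1)
    curve = lag_specific_or(fit, cb, x, x_ref)
    assert np.allclose(C @ fit.coef("crossbasis"), curve.log_or)


def test_curve_frame_round_trip(fitted_dlnm):
    fit, cb = fitted_dlnm
    curve = lag_specific_or(fit, cb, 20.0, 14.2)
    frame = curve_to_frame(curve)
    assert np.allclose(frame["or"], curve.or_)
    assert np.allclose(frame["lo"], curve.lo)
    assert list(frame["week"]) == list(curve.weeks)
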