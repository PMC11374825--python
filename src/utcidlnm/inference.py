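"""Odds-ratio curves, cumulative odds ratios and critical-window detection
from a fitted cross-basis model.

A fitted DLNM reports, for a prediction exposure ``x`` against a reference
``x_ref`` (the cohort median by default), the week-specific log odds ratio

    d_eta(w) = (Bx(x) - Bx(x_ref)) (x) Blag(w) . beta_cb

with delta-method standard errors from the coefficient covariance, and the
cumulative odds ratio over a week set as ``exp`` of the summed contrast.
Critical windows are maximal consecutive runs of weeks whose 95% CI
excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basis import CrossBasis, natural_spline_basis
from .fit import FitResult

__all__ = [
    "LagORCurve",
    "CumulativeOR",
    "CriticalWindow",
    "Z95",
    "lag_specific_or",
    "cumulative_or",
    "detect_critical_windows",
    "curve_to_frame",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile (Wald 95% CI)


@dataclass
class LagORCurve:
    """Week-specific odds ratios at exposure ``x`` versus ``x_ref``."""

    weeks: np.ndarray
    x: float
    x_ref: float
    log_or: np.ndarray
    se: np.ndarray
    extrapolated: bool = False

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.log_or)

    @property
    def lo(self) -> np.ndarray:
        return np.exp(self.log_or - Z95 * self.se)

    @property
    def hi(self) -> np.ndarray:
        return np.exp(self.log_or + Z95 * self.se)


@dataclass
class CumulativeOR:
    """Odds ratio for exposure held at ``x`` over a whole week set."""

    weeks: np.ndarray
    x: float
    x_ref: float
    log_or: float
    se: float

    @property
    def or_(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_or - Z95 * self.se)),
            float(np.exp(self.log_or + Z95 * self.se)),
        )


@dataclass
class CriticalWindow:
    start: int
    end: int
    direction: str  # "harmful" | "protective"


def _contrast_rows(cb: CrossBasis, x: float, x_ref: float, weeks: np.ndarray) -> np.ndarray:
    """(L, df_x*df_lag) matrix of per-week contrast vectors."""
    B = natural_spline_basis(np.array([x, x_ref], dtype=float), cb.x_spec)
    dBx = B[0] - B[1]  # (df_x,)
    Blag = natural_spline_basis(weeks.astype(float), cb.lag_spec)  # (L, df_lag)
    # column (j, k) -> j * df_lag + k
    return np.einsum("j,lk->ljk", dBx, Blag).reshape(weeks.size, -1)


def _check_match(fit: FitResult, cb: CrossBasis, block: str) -> None:
    if block not in fit.blocks:
        raise KeyError(f"fit has no block {block!r}")
    s = fit.blocks[block]
    if s.stop - s.start != cb.matrix.shape[1]:
        raise ValueError("cross-basis column count does not match the fitted block")
    h = fit.meta.get("crossbasis_hash")
    if h is not None and h != cb.hash():
        raise ValueError("cross-basis spec hash does not match the one used in the fit")


def lag_specific_or(
    fit: FitResult,
    cb: CrossBasis,
    x: float,
    x_ref: float,
    weeks: Sequence[int] | None = None,
    block: str = "crossbasis",
) -> LagORCurve:
    """Week-specific OR curve at ``x`` vs ``x_ref`` with delta-method CIs."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    _check_match(fit, cb, block)
    w = cb.lags if weeks is None else np.asarray(weeks, dtype=int)
    C = _contrast_rows(cb, float(x), float(x_ref), w)
    beta = fit.coef(block)
    V = fit.cov_block(block)
    log_or = C @ beta
    se = np.sqrt(np.maximum(np.einsum("lj,jk,lk->l", C, V, C), 0.0))
    a, b = cb.x_spec.boundary_knots
    return LagORCurve(
        weeks=w, x=float(x), x_ref=float(x_ref), log_or=log_or, se=se,
        extrapolated=bool(x < a or x > b),
    )


def cumulative_or(
    fit: FitResult,
    cb: CrossBasis,
    x: float,
    x_ref: float,
    weeks: Sequence[int] | None = None,
    block: str = "crossbasis",
) -> CumulativeOR:
    """Cumulative OR over a week set: the summed weekly contrast, so
    ``log OR_W = sum_w d_eta(w)`` exactly."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    _check_match(fit, cb, block)
    w = cb.lags if weeks is None else np.asarray(weeks, dtype=int)
    if w.size == 0:
        raise ValueError("empty week set")
    C = _contrast_rows(cb, float(x), float(x_ref), w)
    c = C.sum(axis=0)
    beta = fit.coef(block)
    V = fit.cov_block(block)
    return CumulativeOR(
        weeks=w, x=float(x), x_ref=float(x_ref),
        log_or=float(c @ beta), se=float(np.sqrt(max(c @ V @ c, 0.0))),
    )


def detect_critical_windows(curve: LagORCurve, min_run: int = 1) -> list[CriticalWindow]:
    """Maximal consecutive runs of weeks whose 95% CI excludes 1,
    split by direction; runs shorter than ``min_run`` are dropped."""
    lo, hi = curve.lo, curve.hi
    state = np.where(lo > 1.0, 1, np.where(hi < 1.0, -1, 0))
    out: list[CriticalWindow] = []
    i = 0
    n = state.size
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i] and curve.weeks[j + 1] == curve.weeks[j] + 1:
            j += 1
        if j - i + 1 >= min_run:
            out.append(
                CriticalWindow(
                    start=int(curve.weeks[i]),
                    end=int(curve.weeks[j]),
                    direction="harmful" if state[i] == 1 else "protective",
                )
            )
        i = j + 1
    return out


def curve_to_frame(curve: LagORCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "week": curve.weeks,
            "log_or": curve.log_or,
            "or": curve.or_,
            "lo": curve.lo,
            "hi": curve.hi,
            "se": curve.se,
            "x": curve.x,
            "x_ref": curve.x_ref,
        }
    )
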