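"""Cumulative-exposure (one-basis) logistic models for summary periods.

Each period-average exposure (preconception, pregnancy, trimesters) is
expanded through its own natural-spline one-basis (default df 4, knots from
that period's observed distribution); odds ratios at configured centile
levels versus the median follow from the one-basis contrast
``(B(x) - B(x_ref))' beta`` with delta-method CIs.  Preconception and
entire-pregnancy exposures can be fitted simultaneously in one model, as
can the three trimester averages; a separate-models mode fits one period at
a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import OneBasis, SplineSpec, build_one_basis
from .exposure import CentileSet
from .fit import (
    FitResult,
    ModelDesign,
    RankDeficiencyError,
    fit_logistic,
)
from .inference import Z95

__all__ = [
    "PeriodModelResult",
    "fit_period_model",
    "fit_trimester_models",
    "period_or",
]

TRIMESTERS = ("trimester1", "trimester2", "trimester3")


@dataclass
class PeriodModelResult:
    """One fitted period model plus its OR table at the centile levels."""

    fit: FitResult
    bases: dict[str, OneBasis]
    table: pd.DataFrame  # period, centile, level, or, lo, hi
    mode: str  # "simultaneous" | "separate"
    n_used: int = 0

    def spec_hashes(self) -> dict[str, str]:
        return {k: b.hash() for k, b in self.bases.items()}


def period_or(
    fit: FitResult, basis: OneBasis, block: str, x: float, x_ref: float
) -> tuple[float, float, float]:
    """OR and 95% CI at level ``x`` versus ``x_ref`` for one period block."""
    c = basis.predict_contrast(float(x), float(x_ref))
    beta = fit.coef(block)
    V = fit.cov_block(block)
    log_or = float(c @ beta)
    se = float(np.sqrt(max(c @ V @ c, 0.0)))
    return np.exp(log_or), np.exp(log_or - Z95 * se), np.exp(log_or + Z95 * se)


def _assemble(y, blocks: dict[str, OneBasis], covariates) -> ModelDesign:
    n = y.size
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    slices = {"intercept": slice(0, 1)}
    start = 1
    for name, ob in blocks.items():
        parts.append(ob.matrix)
        names += [f"{name}_ns{j + 1}" for j in range(ob.spec.df)]
        slices[name] = slice(start, start + ob.spec.df)
        start += ob.spec.df
    if covariates is not None:
        Xc, cn = covariates
        if Xc.shape[1]:
            parts.append(Xc)
            names += list(cn)
            slices["covariates"] = slice(start, start + Xc.shape[1])
    return ModelDesign(y=y, X=np.hstack(parts), column_names=names, blocks=slices)


def _or_table(
    fit: FitResult, bases: dict[str, OneBasis], centiles: CentileSet, x_ref: float
) -> pd.DataFrame:
    rows = []
    for period, ob in bases.items():
        for label, level in centiles.levels().items():
            o, lo, hi = period_or(fit, ob, period, level, x_ref)
            rows.append(
                {"period": period, "centile": label, "level": level,
                 "or": o, "lo": lo, "hi": hi}
            )
    return pd.DataFrame(rows)


def _condition_diagnostics(design: ModelDesign) -> str:
    s = np.linalg.svd(design.X - design.X.mean(axis=0), compute_uv=False)
    cond = s[0] / s[-1] if s[-1] > 0 else np.inf
    return f"design condition number {cond:.3g}"


def fit_period_model(
    period_table: pd.DataFrame,
    y: np.ndarray,
    covariates: tuple[np.ndarray, list[str]] | None = None,
    periods: tuple[str, ...] = ("preconception", "pregnancy"),
    df: int = 4,
    centiles: CentileSet | None = None,
    x_ref: float | None = None,
    simultaneous: bool = True,
    specs: dict[str, SplineSpec] | None = None,
) -> PeriodModelResult | dict[str, PeriodModelResult]:
    """Fit cumulative-exposure logistic models for the named periods.

    Simultaneous mode puts every requested period's one-basis in a single
    design (the default pairing: preconception + entire pregnancy); separate
    mode fits one model per period and returns a dict keyed by period.
    Rows with a missing period average are dropped listwise.
    """
    missing = [p for p in periods if p not in period_table.columns]
    if missing:
        raise KeyError(f"period columns not present: {missing}")
    y = np.asarray(y, dtype=float)

    if centiles is None:
        centiles = CentileSet(
            p1=10.2, p5=11.9, median=14.2, mean=14.5, p95=17.4, p99=26.0,
            source="configured defaults",
        )
    if x_ref is None:
        x_ref = centiles.median

    def one(pset: tuple[str, ...], mode: str) -> PeriodModelResult:
        cols = period_table[list(pset)].to_numpy(dtype=float)
        ok = np.all(np.isfinite(cols), axis=1)
        if covariates is not None:
            Xc, cn = covariates
            cov_ok = (Xc[ok], cn)
        else:
            cov_ok = None
        bases = {}
        for i, p in enumerate(pset):
            spec = (specs or {}).get(p)
            bases[p] = build_one_basis(cols[ok, i], spec=spec, df=df, centre=x_ref)
        design = _assemble(y[ok], bases, cov_ok)
        try:
            fit = fit_logistic(design)
        except RankDeficiencyError as e:
            raise RankDeficiencyError(f"{e} [{_condition_diagnostics(design)}]") from None
        return PeriodModelResult(
            fit=fit, bases=bases, table=_or_table(fit, bases, centiles, x_ref),
            mode=mode, n_used=int(ok.sum()),
        )

    if simultaneous:
        return one(tuple(periods), "simultaneous")
    return {p: one((p,), "separate") for p in periods}


def fit_trimester_models(
    period_table: pd.DataFrame,
    y: np.ndarray,
    covariates: tuple[np.ndarray, list[str]] | None = None,
    mode: str = "simultaneous",
    df: int = 4,
    centiles: CentileSet | None = None,
    x_ref: float | None = None,
) -> pd.DataFrame:
    """Trimester-specific one-basis models, simultaneous or separate.

    Returns a single OR table (period x centile) tagged with the mode.
    Subjects whose follow-up ends before a trimester contribute no row to
    models that include that trimester.
    """
    if mode not in ("simultaneous", "separate"):
        raise ValueError(f"mode must be 'simultaneous' or 'separate', got {mode!r}")
    res = fit_period_model(
        period_table, y, covariates, periods=TRIMESTERS, df=df,
        centiles=centiles, x_ref=x_ref, simultaneous=(mode == "simultaneous"),
    )
    if mode == "simultaneous":
        table = res.table.copy()
    else:
        table = pd.concat([r.table for r in res.values()], ignore_index=True)
    table["mode"] = mode
    return table
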