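"""Natural cubic spline bases and the distributed-lag cross-basis.

The distributed-lag non-linear model (DLNM) represents the effect of a
time-varying exposure as a smooth surface over exposure intensity and lag.
Its design-matrix core is the *cross-basis*: the lag-summed tensor product
of a spline basis in the exposure dimension and a spline basis in the lag
dimension.  A *one-basis* is the unidimensional analogue used for
cumulative-exposure (period-average) models.

Both use natural (restricted) cubic splines: piecewise cubic between the
knots, constrained to be linear beyond the boundary knots, with continuous
second derivatives everywhere.  For a spline with ``df`` degrees of freedom
the interior knots sit at equally spaced quantiles of the observed values
and the boundary knots at the observed min/max; no intercept column is
included (models carry a single global intercept).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "natural_spline_basis",
    "OneBasis",
    "CrossBasis",
    "build_one_basis",
    "build_cross_basis",
    "cross_basis_from_marginals",
]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a natural cubic spline basis.

    Parameters
    ----------
    df
        Number of basis columns (positive).  A natural spline with ``df``
        columns has ``df - 1`` interior knots.
    interior_knots
        Ordered knot positions strictly inside the boundary knots.
    boundary_knots
        ``(lower, upper)`` pair; the basis is linear beyond these.
    centre
        Optional centring value: predictions subtract the basis evaluated
        here so the fitted curve is zero at ``centre``.
    intercept
        When True the basis spans constants (used for the lag dimension of
        a cross-basis, where a lag-constant effect must be representable);
        ``df`` still counts the total columns, so there are ``df - 2``
        interior knots instead of ``df - 1``.
    """

    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    centre: float | None = None
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if self.intercept and self.df < 2:
            raise ValueError("an intercept basis needs df >= 2")
        need = self.df - 2 if self.intercept else self.df - 1
        if len(self.interior_knots) != need:
            raise ValueError(
                f"a natural spline with df={self.df} (intercept={self.intercept}) "
                f"needs {need} interior knots, got {len(self.interior_knots)}"
            )
        a, b = self.boundary_knots
        if not a < b:
            raise ValueError(f"boundary knots must be increasing, got {self.boundary_knots}")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and (np.any(ik <= a) | np.any(ik >= b)):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        if ik.size > 1 and np.any(np.diff(ik) < 0):
            raise ValueError("interior knots must be ordered")

    @classmethod
    def from_values(
        cls,
        values: Sequence[float],
        df: int,
        centre: float | None = None,
        intercept: bool = False,
    ) -> "SplineSpec":
        """Place knots from data: interior knots at equally spaced quantiles,
        boundary knots at the observed min/max."""
        x = np.asarray(values, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError("no finite values to place knots from")
        lo, hi = float(x.min()), float(x.max())
        if not lo < hi:
            raise ValueError("values are constant; cannot place boundary knots")
        if df < 1:
            raise ValueError(f"df must be >= 1, got {df}")
        m = (df - 2 if intercept else df - 1) + 1
        probs = np.arange(1, m) / m
        interior = tuple(float(q) for q in np.quantile(x, probs))
        return cls(
            df=df, interior_knots=interior, boundary_knots=(lo, hi),
            centre=centre, intercept=intercept,
        )

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
            "centre": self.centre,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            df=int(d["df"]),
            interior_knots=tuple(float(k) for k in d["interior_knots"]),
            boundary_knots=(float(d["boundary_knots"][0]), float(d["boundary_knots"][1])),
            centre=None if d.get("centre") is None else float(d["centre"]),
            intercept=bool(d.get("intercept", False)),
        )

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cubic_bspline_design(x: np.ndarray, spec: SplineSpec, deriv: int = 0) -> np.ndarray:
    """Unconstrained cubic B-spline design matrix on the spec's knot set."""
    a, b = spec.boundary_knots
    t = np.concatenate(([a] * 4, np.asarray(spec.interior_knots, float), [b] * 4))
    nb = len(spec.interior_knots) + 4
    bs = BSpline(t, np.eye(nb), 3, extrapolate=True)
    if deriv:
        bs = bs.derivative(deriv)
    return bs(x)


def natural_spline_basis(values: Sequence[float], spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``values``.

    Returns an ``(n, df)`` matrix.  Points beyond the boundary knots are
    evaluated by the first-order Taylor extension at the boundary, which is
    exact because the natural spline is linear there.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("spline input contains non-finite values")
    a, b = spec.boundary_knots
    xc = np.clip(x, a, b)
    B = _cubic_bspline_design(xc, spec)

    outside = (x < a) | (x > b)
    if np.any(outside):
        xo = x[outside]
        edge = np.where(xo < a, a, b)
        B0 = _cubic_bspline_design(edge, spec)
        B1 = _cubic_bspline_design(edge, spec, deriv=1)
        B[outside] = B0 + B1 * (xo - edge)[:, None]

    # Natural constraints: zero second derivative at both boundary knots.
    # Without an intercept, drop the first B-spline column, then project
    # the rest onto the null space of the constraint matrix.
    j0 = 0 if spec.intercept else 1
    const = _cubic_bspline_design(np.array([a, b]), spec, deriv=2)[:, j0:]
    Q, _ = np.linalg.qr(const.T, mode="complete")
    out = B[:, j0:] @ Q[:, 2:]
    return out


@dataclass
class OneBasis:
    """A natural-spline expansion of a single summary exposure."""

    matrix: np.ndarray
    spec: SplineSpec

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != self.spec.df:
            raise ValueError("column count does not match spec df")

    def predict_contrast(self, x: float, x_ref: float) -> np.ndarray:
        """Contrast vector ``B(x) - B(x_ref)`` for odds-ratio prediction."""
        B = natural_spline_basis([x, x_ref], self.spec)
        return B[0] - B[1]

    def hash(self) -> str:
        return self.spec.hash()


@dataclass
class CrossBasis:
    """Lag-summed tensor-product design block of a DLNM.

    ``matrix[i, j*df_lag + k] = sum_l Bx[x_il, j] * Blag[lag_l, k]`` where
    ``Bx`` is the exposure-dimension natural spline and ``Blag`` the
    lag-dimension natural spline evaluated on the integer week grid.
    """

    matrix: np.ndarray
    x_spec: SplineSpec
    lag_spec: SplineSpec
    lags: np.ndarray = field(default=None)  # integer week indices, ordered

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        if self.matrix.shape[1] != self.x_spec.df * self.lag_spec.df:
            raise ValueError("column count must be df_x * df_lag")

    @property
    def df_x(self) -> int:
        return self.x_spec.df

    @property
    def df_lag(self) -> int:
        return self.lag_spec.df

    def lag_basis(self, weeks: Sequence[int] | None = None) -> np.ndarray:
        w = self.lags if weeks is None else np.asarray(weeks)
        return natural_spline_basis(w.astype(float), self.lag_spec)

    def hash(self) -> str:
        payload = json.dumps(
            {
                "x": self.x_spec.to_dict(),
                "lag": self.lag_spec.to_dict(),
                "lags": self.lags.tolist(),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_one_basis(
    values: Sequence[float],
    spec: SplineSpec | None = None,
    df: int = 4,
    centre: float | None = None,
) -> OneBasis:
    """Expand a summary-exposure vector through a natural spline basis."""
    x = np.asarray(values, dtype=float)
    if spec is None:
        spec = SplineSpec.from_values(x, df=df, centre=centre)
    return OneBasis(matrix=natural_spline_basis(x, spec), spec=spec)


def build_cross_basis(
    weekly_values: np.ndarray,
    weeks: Sequence[int],
    x_spec: SplineSpec | None = None,
    lag_spec: SplineSpec | None = None,
    df_x: int = 4,
    df_lag: int = 3,
    knot_values: np.ndarray | None = None,
) -> CrossBasis:
    """Build the DLNM cross-basis from a complete weekly exposure matrix.

    Parameters
    ----------
    weekly_values
        ``(n_subjects, n_weeks)`` matrix, already padded to the full lag
        range (no masked gaps).
    weeks
        Integer week indices for the columns (e.g. ``-11 .. 42``).
    x_spec, lag_spec
        Explicit spline specs; when omitted they are placed from the data
        (``df_x`` quantile knots on the exposure values — or on
        ``knot_values`` when supplied, e.g. the unpadded observations —
        ``df_lag`` quantile knots on the week index).
    """
    X = np.asarray(weekly_values, dtype=float)
    w = np.asarray(weeks, dtype=int)
    if X.ndim != 2 or X.shape[1] != w.size:
        raise ValueError(
            f"weekly matrix has {X.shape[1] if X.ndim == 2 else '?'} columns "
            f"but {w.size} week indices were given"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("weekly exposure matrix contains non-finite values; pad it first")
    if x_spec is None:
        src = X if knot_values is None else np.asarray(knot_values, float)
        x_spec = SplineSpec.from_values(src.ravel(), df=df_x)
    if lag_spec is None:
        # The lag basis spans constants (intercept=True) so lag-constant
        # effects are representable; the model intercept absorbs the
        # resulting global shift.
        lag_spec = SplineSpec.from_values(w.astype(float), df=df_lag, intercept=True)

    n, L = X.shape
    Bx = natural_spline_basis(X.ravel(), x_spec).reshape(n, L, x_spec.df)
    Blag = natural_spline_basis(w.astype(float), lag_spec)  # (L, df_lag)
    M = cross_basis_from_marginals(Bx, Blag)
    return CrossBasis(matrix=M, x_spec=x_spec, lag_spec=lag_spec, lags=w)


def cross_basis_from_marginals(Bx: np.ndarray, Blag: np.ndarray) -> np.ndarray:
    """Lag-summed tensor product of explicit marginal bases.

    ``Bx`` is ``(n, L, df_x)`` (exposure basis at every subject-week),
    ``Blag`` is ``(L, df_lag)``; returns ``(n, df_x * df_lag)`` with the
    exposure index outer and the lag index inner.
    """
    n, L, df_x = Bx.shape
    return np.einsum("nlj,lk->njk", Bx, Blag).reshape(n, df_x * Blag.shape[1])
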