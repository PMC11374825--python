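"""Binomial-logit likelihood fitting and AIC-based basis selection.

The fitter is a plain iteratively reweighted least squares (IRLS)
maximiser of the Bernoulli log-likelihood with step-halving when a step
decreases the likelihood, convergence declared on the score max-norm, and
the variance-covariance matrix taken as the inverse observed information
at the optimum.  Rank deficiency and separation are raised as explicit
errors, never returned silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import linalg

from .basis import SplineSpec, natural_spline_basis, build_cross_basis
from .exposure import WeeklyExposureMatrix

__all__ = [
    "ModelDesign",
    "FitResult",
    "RankDeficiencyError",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "fit_design",
    "build_covariate_design",
    "select_df_by_aic",
    "REFERENCE_LEVELS",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is not of full column rank."""


class SeparationError(RuntimeError):
    """The likelihood is maximised at infinity (perfect separation)."""


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the score tolerance within max_iter."""


# Fixed (arbitrary but documented) reference levels for indicator coding.
# Exposure odds ratios are invariant to this choice.
REFERENCE_LEVELS = {
    "infant_sex": "female",
    "race": "non-Caucasian",
    "marital": "unmarried",
    "smoking": "non-smoker",
    "parity": "nulliparous",
    "remoteness": "non-urban",
    "ses": "high",
}


@dataclass
class ModelDesign:
    """Outcome vector plus a named-block design matrix."""

    y: np.ndarray
    X: np.ndarray
    column_names: list[str]
    blocks: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("row mismatch between outcome and design")
        if not np.all((self.y == 0) | (self.y == 1)):
            raise ValueError("outcome must be binary 0/1")
        if len(self.column_names) != self.X.shape[1]:
            raise ValueError("column_names length mismatch")

    def block_slice(self, name: str) -> slice:
        return self.blocks[name]


@dataclass
class FitResult:
    """Maximum-likelihood fit of a binomial-logit model."""

    beta: np.ndarray
    cov: np.ndarray  # inverse observed information
    loglik: float
    converged: bool
    n_iter: int
    column_names: list[str]
    blocks: dict[str, slice] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)  # e.g. cross-basis spec hash

    @property
    def n_params(self) -> int:
        return self.beta.size

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def coef(self, block: str) -> np.ndarray:
        return self.beta[self.blocks[block]]

    def cov_block(self, block: str) -> np.ndarray:
        s = self.blocks[block]
        return self.cov[s, s]

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "column_names": list(self.column_names),
            "blocks": {k: [v.start, v.stop] for k, v in self.blocks.items()},
            "meta": self.meta,
        }


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: sum y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} of {X.shape[1]}); "
            f"offending columns: {bad}"
        )


def fit_logistic(
    design: ModelDesign,
    tol: float = 1e-8,
    max_iter: int = 100,
    check_rank: bool = True,
) -> FitResult:
    """IRLS maximum-likelihood fit of a logistic regression.

    Convergence requires the score max-norm below ``tol``; steps that
    decrease the log-likelihood are halved (up to 30 times).  Raises
    :class:`SeparationError` when fitted probabilities collapse onto the
    labels and :class:`ConvergenceError` on a stalled fit.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than coefficients ({p})")
    if check_rank:
        _check_rank(X, design.column_names)

    beta = np.zeros(p)
    if "intercept" in design.column_names:
        j = design.column_names.index("intercept")
        ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
        beta[j] = np.log(ybar / (1 - ybar))
    eta = X @ beta
    ll = _loglik(y, eta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = linalg.solve(H, score, assume_a="pos")
        except linalg.LinAlgError:
            raise SeparationError(
                "observed information is singular at the current iterate; "
                "data are separated or the model is degenerate"
            )
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            eta_c = X @ cand
            ll_c = _loglik(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            factor /= 2.0
        beta, eta, ll = cand, eta_c, ll_c

    mu = expit(eta)
    if converged and np.all(np.abs(y - mu) < 1e-6):
        # score can vanish at a divergent beta when classes are separable
        raise SeparationError(
            "perfect separation: fitted probabilities equal the observed labels"
        )
    if not converged:
        # diagnose separation: fitted probabilities collapsing onto labels
        if np.mean(np.abs(y - mu) < 1e-6) > 0.99 or np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "perfect or quasi-perfect separation detected: fitted "
                "probabilities collapse onto the observed labels"
            )
        raise ConvergenceError(
            f"IRLS did not reach score tolerance {tol} in {max_iter} iterations "
            f"(score max-norm {np.max(np.abs(X.T @ (y - mu))):.3e})"
        )
    w = mu * (1 - mu)
    H = X.T @ (X * w[:, None])
    cov = linalg.inv(H)
    cov = (cov + cov.T) / 2
    return FitResult(
        beta=beta,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        column_names=list(design.column_names),
        blocks=dict(design.blocks),
    )


def build_covariate_design(
    cohort: pd.DataFrame,
    maternal_age_df: int = 3,
    maternal_age_as: str = "spline",  # "spline" | "categorical"
    season_as: str = "month",  # "month" | "four_season" | None
    year_as: str = "categorical",  # "categorical" | "continuous"
    drop: tuple[str, ...] = (),
    age_spec: SplineSpec | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Adjustment block: indicator coding for the categorical covariates
    (fixed reference levels), natural-spline (default df 3) or categorical
    maternal age, and conception month/year terms.

    Returns ``(X, names, complete_mask)`` where ``complete_mask`` flags rows
    with no unknown covariate values (others are dropped listwise by
    callers).
    """
    n = len(cohort)
    cols: list[np.ndarray] = []
    names: list[str] = []
    complete = np.ones(n, dtype=bool)

    for var, ref in REFERENCE_LEVELS.items():
        if var in drop or var not in cohort.columns:
            continue
        vals = cohort[var].astype(str).to_numpy()
        complete &= vals != "unknown"
        for level in sorted(set(vals) - {ref, "unknown"}):
            cols.append((vals == level).astype(float))
            names.append(f"{var}={level}")

    if "maternal_age" in cohort.columns and "maternal_age" not in drop:
        age = cohort["maternal_age"].to_numpy(dtype=float)
        complete &= np.isfinite(age)
        safe_age = np.where(np.isfinite(age), age, np.nanmedian(age))
        if maternal_age_as == "spline":
            spec = age_spec or SplineSpec.from_values(
                safe_age[complete], df=maternal_age_df
            )
            B = natural_spline_basis(safe_age, spec)
            for j in range(B.shape[1]):
                cols.append(B[:, j])
                names.append(f"maternal_age_ns{j + 1}")
        else:  # categorical <=19 / 20-34 / >=35, reference 20-34
            cols.append((safe_age <= 19).astype(float))
            names.append("maternal_age<=19")
            cols.append((safe_age >= 35).astype(float))
            names.append("maternal_age>=35")

    if season_as and "conception_month" in cohort.columns and "season" not in drop:
        month = cohort["conception_month"].to_numpy(dtype=int)
        if season_as == "month":
            for m in range(2, 13):  # January is the reference month
                cols.append((month == m).astype(float))
                names.append(f"conception_month={m}")
        elif season_as == "four_season":
            # Southern Hemisphere meteorological seasons; summer (Dec-Feb)
            # is the reference.
            seasons = {"autumn": (3, 4, 5), "winter": (6, 7, 8), "spring": (9, 10, 11)}
            for s, ms in seasons.items():
                cols.append(np.isin(month, ms).astype(float))
                names.append(f"season={s}")
        else:
            raise ValueError(f"unknown season_as {season_as!r}")

    if "conception_year" in cohort.columns and "conception_year" not in drop:
        year = cohort["conception_year"].to_numpy(dtype=int)
        if year_as == "categorical":
            levels = sorted(set(year))[1:]
            for yv in levels:
                cols.append((year == yv).astype(float))
                names.append(f"conception_year={yv}")
        else:
            cols.append((year - year.min()).astype(float))
            names.append("conception_year_index")

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names, complete


def assemble_design(
    y: np.ndarray,
    exposure_block: np.ndarray,
    exposure_names: list[str],
    covariates: tuple[np.ndarray, list[str]] | None = None,
    block_name: str = "exposure",
) -> ModelDesign:
    """Intercept + exposure block (+ covariate block) model design."""
    n = len(y)
    parts = [np.ones((n, 1)), exposure_block]
    names = ["intercept"] + list(exposure_names)
    blocks = {
        "intercept": slice(0, 1),
        block_name: slice(1, 1 + exposure_block.shape[1]),
    }
    if covariates is not None:
        Xc, cn = covariates
        if Xc.shape[1]:
            start = 1 + exposure_block.shape[1]
            parts.append(Xc)
            names += list(cn)
            blocks["covariates"] = slice(start, start + Xc.shape[1])
    return ModelDesign(y=y, X=np.hstack(parts), column_names=names, blocks=blocks)


def fit_design(design: ModelDesign, **kw) -> FitResult:
    return fit_logistic(design, **kw)


def select_df_by_aic(
    weekly: WeeklyExposureMatrix,
    y: np.ndarray,
    covariates: tuple[np.ndarray, list[str]] | None = None,
    grid: list[tuple[int, int]] | None = None,
) -> tuple[tuple[int, int], pd.DataFrame]:
    """Refit the DLNM over a (df_x, df_lag) grid and pick the lowest AIC.

    Returns the winning pair and the full AIC table (fits that fail are
    recorded with NaN AIC and excluded from the argmin).
    """
    if grid is None:
        grid = [(i, j) for i in range(2, 8) for j in range(2, 8)]
    if not grid:
        raise ValueError("empty df grid")
    rows = []
    obs = weekly.observed_values()
    for df_x, df_lag in grid:
        try:
            cb = build_cross_basis(
                weekly.values, weekly.weeks, df_x=df_x, df_lag=df_lag, knot_values=obs
            )
            names = [f"cb_{j}_{k}" for j in range(df_x) for k in range(df_lag)]
            design = assemble_design(y, cb.matrix, names, covariates, block_name="crossbasis")
            fit = fit_logistic(design)
            rows.append({"df_x": df_x, "df_lag": df_lag, "aic": fit.aic, "error": ""})
        except (RankDeficiencyError, SeparationError, ConvergenceError, ValueError) as e:
            rows.append({"df_x": df_x, "df_lag": df_lag, "aic": np.nan, "error": str(e)})
    table = pd.DataFrame(rows)
    if table["aic"].isna().all():
        raise RuntimeError("every candidate fit failed during df selection")
    best = table.loc[table["aic"].idxmin()]
    return (int(best["df_x"]), int(best["df_lag"])), table
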