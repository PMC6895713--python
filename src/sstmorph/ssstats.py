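"""Mixed-effects shape models and the lumen scaling prediction.

Two repeated-measures models, each with a random intercept per bird:

* mean diameter (d1+d2)/2 ~ distance + distance^2 + total length
* circularity d1/d2 ~ total length + (d1+d2) + distance + (d1+d2):distance

plus an ordinary least-squares line relating lumen diameter to outer
diameter, used to predict the lumen width at new outer measurements.

The quadratic distance model can be parameterized on raw micrometre
powers or on orthogonal polynomial scores (R ``poly()`` convention);
estimates of the quadratic term are only comparable within one
parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMResult, fit_random_intercept

__all__ = [
    "TermEstimate",
    "ModelFit",
    "LumenScalingFit",
    "orthogonal_poly",
    "fit_diameter_model",
    "fit_circularity_model",
    "r2_mixed",
    "fit_lumen_scaling",
    "predict_lumen",
]


@dataclass(frozen=True)
class TermEstimate:
    name: str
    estimate: float
    se: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ModelFit:
    """Fixed-effect table plus variance components and r2 of a mixed fit."""

    terms: tuple[TermEstimate, ...]
    sd_bird: float
    sd_residual: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_birds: int
    parameterization: str = "raw"

    def __post_init__(self) -> None:
        if not self.r2_marginal <= self.r2_conditional <= 1.0 + 1e-12:
            raise ValueError(
                f"require r2_marginal <= r2_conditional <= 1, got "
                f"{self.r2_marginal}, {self.r2_conditional}"
            )

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": t.name, "estimate": t.estimate, "se": t.se,
                 "t": t.t, "df": t.df, "p": t.p}
                for t in self.terms
            ]
        )


@dataclass(frozen=True)
class LumenScalingFit:
    """OLS line lumen_diameter = intercept + slope * outer_diameter."""

    intercept: float
    slope: float
    residual_sd: float
    intercept_se: float
    slope_se: float
    n: int
    x_mean: float
    x_sumsq: float  # centered sum of squares of x

    def predict(self, outer_diameter) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(outer_diameter, dtype=float)

    def prediction_se(self, outer_diameter) -> np.ndarray:
        """SE of the fitted mean at new outer diameters."""
        x = np.asarray(outer_diameter, dtype=float)
        lev = 1.0 / self.n + (x - self.x_mean) ** 2 / self.x_sumsq
        return self.residual_sd * np.sqrt(lev)


def orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthogonal polynomial scores matching R's ``poly(x, degree)``.

    Columns are orthogonal to the intercept and to each other, each with
    unit sum of squares.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("x is constant; orthogonal polynomials undefined")
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q[:, 1:] * signs[1:]


def _require_columns(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns: {missing}")


def _mean_diameter(table: pd.DataFrame) -> np.ndarray:
    if "mean_diameter_um" in table.columns:
        return table["mean_diameter_um"].to_numpy(float)
    return 0.5 * (table["d1_um"].to_numpy(float) + table["d2_um"].to_numpy(float))


def _circ(table: pd.DataFrame) -> np.ndarray:
    if "circularity" in table.columns:
        return table["circularity"].to_numpy(float)
    d1 = table["d1_um"].to_numpy(float)
    d2 = table["d2_um"].to_numpy(float)
    return np.maximum(d1, d2) / np.minimum(d1, d2)


def _to_modelfit(res: LMMResult, parameterization: str = "raw") -> ModelFit:
    r2m, r2c = r2_mixed(res)
    terms = tuple(
        TermEstimate(
            name=res.names[i],
            estimate=float(res.beta[i]),
            se=float(res.se[i]),
            t=float(res.tvalues[i]),
            df=float(res.df[i]),
            p=float(res.pvalues[i]),
        )
        for i in range(len(res.names))
    )
    return ModelFit(
        terms=terms,
        sd_bird=res.tau,
        sd_residual=res.sigma,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=res.n_obs,
        n_birds=res.n_groups,
        parameterization=parameterization,
    )


def fit_diameter_model(table: pd.DataFrame, parameterization: str = "raw") -> ModelFit:
    """Mixed model of mean cross-section diameter along the tubule.

    Fixed effects: distance from the orifice (linear + quadratic) and
    total tubule length; random intercept per bird; REML.

    Parameters
    ----------
    table : rows per bird x sample point with columns ``bird_id``, ``s_um``,
        ``total_length_um`` and either ``mean_diameter_um`` or ``d1_um``/
        ``d2_um``.
    parameterization : "raw" fits on s and s^2 in um; "orthogonal" fits on
        degree-1/2 orthogonal polynomial scores of s.
    """
    _require_columns(table, ["bird_id", "s_um", "total_length_um"])
    y = _mean_diameter(table)
    s = table["s_um"].to_numpy(float)
    length = table["total_length_um"].to_numpy(float)
    n = len(table)
    if parameterization == "raw":
        X = np.column_stack([np.ones(n), s, s**2, length])
        names = ("intercept", "distance", "distance_sq", "total_length")
    elif parameterization == "orthogonal":
        P = orthogonal_poly(s, 2)
        X = np.column_stack([np.ones(n), P, length])
        names = ("intercept", "poly1_distance", "poly2_distance", "total_length")
    else:
        raise ValueError(f"unknown parameterization: {parameterization!r}")
    res = fit_random_intercept(y, X, table["bird_id"].to_numpy(), names=names)
    return _to_modelfit(res, parameterization)


def fit_circularity_model(table: pd.DataFrame) -> ModelFit:
    """Mixed model of the circularity index d1/d2.

    Fixed effects: total length, d1+d2, distance from the orifice, and
    the (d1+d2):distance interaction; random intercept per bird; REML.
    """
    _require_columns(table, ["bird_id", "s_um", "total_length_um", "d1_um", "d2_um"])
    y = _circ(table)
    s = table["s_um"].to_numpy(float)
    dsum = table["d1_um"].to_numpy(float) + table["d2_um"].to_numpy(float)
    length = table["total_length_um"].to_numpy(float)
    n = len(table)
    X = np.column_stack([np.ones(n), length, dsum, s, dsum * s])
    names = ("intercept", "total_length", "d_sum", "distance", "d_sum:distance")
    res = fit_random_intercept(y, X, table["bird_id"].to_numpy(), names=names)
    return _to_modelfit(res)


def r2_mixed(res: LMMResult) -> tuple[float, float]:
    """Marginal and conditional r2 by the Gaussian variance decomposition.

    marginal = var(fixed predictions) / (var_fixed + var_intercept +
    var_residual); conditional adds the random-intercept variance to the
    numerator.
    """
    var_f = float(np.var(res.fitted_fixed, ddof=1)) if res.n_obs > 1 else 0.0
    total = var_f + res.tau**2 + res.sigma**2
    if total <= 0:
        raise ValueError("total variance is zero; r2 undefined")
    return var_f / total, (var_f + res.tau**2) / total


def fit_lumen_scaling(outer_diameter, lumen_diameter) -> LumenScalingFit:
    """OLS line relating lumen diameter to outer tubule diameter (um)."""
    x = np.asarray(outer_diameter, dtype=float)
    y = np.asarray(lumen_diameter, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("outer and lumen diameters must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("outer diameters are constant; slope undefined")
    slope, intercept, _, _, slope_se = stats.linregress(x, y)
    resid = y - (intercept + slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    intercept_se = residual_sd * np.sqrt(1.0 / n + x.mean() ** 2 / sxx)
    return LumenScalingFit(
        intercept=float(intercept),
        slope=float(slope),
        residual_sd=residual_sd,
        intercept_se=float(intercept_se),
        slope_se=float(slope_se),
        n=n,
        x_mean=float(x.mean()),
        x_sumsq=sxx,
    )


def predict_lumen(fit: LumenScalingFit, outer_diameter) -> np.ndarray:
    """Predicted lumen diameter (um) at the given outer diameters."""
    return fit.predict(outer_diameter)
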