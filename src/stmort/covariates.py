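"""Covariate trend fitting and projection to the horizon year.

Each covariate series (wealth index, years of schooling, urbanization) is
fit per province and sex with a natural cubic spline; beyond the observed
span the series continues linearly with the boundary derivative.  Projected
urbanization is clamped to [0, 1] and years of schooling floored at zero;
observed values are never modified.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .synthetic import COVARIATES

logger = logging.getLogger(__name__)


class CovariateTrend(RegressorMixin, BaseEstimator):
    """Natural cubic spline through one (year, value) series with linear tails.

    With fewer than four observations the fit falls back to a straight line
    (logged).  ``predict`` evaluates the spline inside the observed span and
    continues linearly outside it, anchored at the boundary value (so the
    extension is continuous); the extrapolation slope is the least-squares
    trend over the ``slope_window`` years nearest the boundary, which is far
    more robust to end-point noise than the interpolant's derivative.
    """

    def __init__(self, min_points: int = 4, slope_window: int = 5):
        self.min_points = min_points
        self.slope_window = slope_window

    def fit(self, X, y):
        years = np.asarray(X, dtype=float).ravel()
        values = np.asarray(y, dtype=float).ravel()
        if years.size != values.size or years.size < 2:
            raise ValueError("need matching year/value series of length >= 2")
        order = np.argsort(years)
        years, values = years[order], values[order]
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be distinct")
        self.span_ = (float(years[0]), float(years[-1]))
        if years.size < self.min_points:
            logger.warning(
                "CovariateTrend: only %d points, falling back to linear fit",
                years.size)
            slope, intercept = np.polyfit(years, values, 1)
            self._line = (float(slope), float(intercept))
            self._spline = None
            self.boundary_slopes_ = (float(slope), float(slope))
        else:
            self._line = None
            self._spline = CubicSpline(years, values, bc_type="natural")
            # extrapolation slope: least-squares trend over the window
            # nearest the boundary -- far more stable under observation noise
            # than the interpolant's endpoint derivative
            k = min(self.slope_window, years.size)
            left = float(np.polyfit(years[:k], values[:k], 1)[0])
            right = float(np.polyfit(years[-k:], values[-k:], 1)[0])
            self.boundary_slopes_ = (left, right)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "span_")
        t = np.asarray(X, dtype=float).ravel()
        lo, hi = self.span_
        if self._spline is None:
            slope, intercept = self._line
            return slope * t + intercept
        out = self._spline(np.clip(t, lo, hi))
        left, right = self.boundary_slopes_
        out = np.where(t < lo, self._spline(lo) + left * (t - lo), out)
        out = np.where(t > hi, self._spline(hi) + right * (t - hi), out)
        return np.asarray(out, dtype=float)


def fit_covariate_trend(series: pd.DataFrame | list[tuple[float, float]],
                        min_points: int = 4) -> CovariateTrend:
    """Fit one covariate series given (year, value) pairs."""
    if isinstance(series, pd.DataFrame):
        years, values = series["year"].to_numpy(), series.iloc[:, 1].to_numpy()
    else:
        arr = np.asarray(series, dtype=float)
        years, values = arr[:, 0], arr[:, 1]
    return CovariateTrend(min_points=min_points).fit(years, values)


_BOUNDS = {
    "wealth_index": (None, None),
    "years_schooling": (0.0, None),
    "urbanization": (0.0, 1.0),
}


def fit_covariate_trends(
    table: pd.DataFrame,
) -> dict[tuple[str, str, str], CovariateTrend]:
    """One spline per (province, sex, covariate)."""
    trends: dict[tuple[str, str, str], CovariateTrend] = {}
    for (pid, sex), grp in table.groupby(["province_id", "sex"]):
        grp = grp.sort_values("year")
        for cov in COVARIATES:
            trends[(pid, sex, cov)] = CovariateTrend().fit(
                grp["year"].to_numpy(), grp[cov].to_numpy())
    return trends


def project_covariates(
    table: pd.DataFrame,
    trends: dict[tuple[str, str, str], CovariateTrend] | None = None,
    horizon_year: int = 2030,
) -> pd.DataFrame:
    """Extend the covariate table year by year to ``horizon_year``.

    Observed rows pass through untouched; projected urbanization is clamped
    to [0, 1] and years of schooling floored at 0.
    """
    last = int(table["year"].max())
    if horizon_year < last:
        raise ValueError(
            f"horizon_year {horizon_year} precedes last observed year {last}")
    if trends is None:
        trends = fit_covariate_trends(table)
    if horizon_year == last:
        return table.copy()
    future = np.arange(last + 1, horizon_year + 1)
    rows = []
    for (pid, sex), _ in table.groupby(["province_id", "sex"]):
        vals = {}
        for cov in COVARIATES:
            pred = trends[(pid, sex, cov)].predict(future)
            lo, hi = _BOUNDS[cov]
            vals[cov] = np.clip(pred, lo, hi)
        for k, year in enumerate(future):
            rows.append({"year": int(year), "province_id": pid, "sex": sex,
                         **{cov: float(vals[cov][k]) for cov in COVARIATES}})
    return pd.concat([table, pd.DataFrame(rows)], ignore_index=True)
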