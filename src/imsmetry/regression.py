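"""Shared least-squares plumbing for the calibration modules.

All platform calibrations in this package reduce to a straight line in some
transformed space (arrival time vs 1/voltage, log CCS' vs log t', K0 vs
1/Ve, ...).  This module provides one ordinary/weighted least-squares fit
object that carries the uncertainties, residuals and the 95 % prediction
band that the calibration workflows report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import CalibrationError


@dataclass
class LinearFit:
    """y = slope * x + intercept, with OLS/WLS diagnostics.

    The prediction band is for a single future observation, using the
    Student-t quantile at the fit's degrees of freedom, so it widens when few
    calibrants are used.
    """

    slope: float
    intercept: float
    u_slope: float
    u_intercept: float
    r2: float
    residuals: np.ndarray
    dof: int
    s: float                 # residual standard deviation
    x: np.ndarray
    y: np.ndarray
    weights: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def predict(self, x0):
        return self.slope * np.asarray(x0, dtype=float) + self.intercept

    def prediction_halfwidth(self, x0, level: float = 0.95):
        """Half-width of the prediction interval for one new observation at x0."""
        x0 = np.asarray(x0, dtype=float)
        n = len(self.x)
        if self.dof <= 0:
            # interpolating fit: no spread information; band collapses to 0
            return np.zeros_like(x0)
        t = stats.t.ppf(0.5 + level / 2.0, df=self.dof)
        xbar = float(np.mean(self.x))
        sxx = float(np.sum((self.x - xbar) ** 2))
        se = self.s * np.sqrt(1.0 + 1.0 / n + (x0 - xbar) ** 2 / sxx)
        return t * se

    def prediction_interval(self, x0, level: float = 0.95):
        yhat = self.predict(x0)
        hw = self.prediction_halfwidth(x0, level)
        return yhat - hw, yhat + hw

    def studentized_residuals(self) -> np.ndarray:
        """Internally studentized residuals (leverage-corrected)."""
        n = len(self.x)
        xbar = float(np.mean(self.x))
        sxx = float(np.sum((self.x - xbar) ** 2))
        h = 1.0 / n + (self.x - xbar) ** 2 / sxx
        denom = self.s * np.sqrt(np.maximum(1.0 - h, 1e-300))
        if self.s == 0:
            return np.zeros(n)
        return self.residuals / denom

    @property
    def x_range(self):
        return float(np.min(self.x)), float(np.max(self.x))


def fit_line(x, y, u_y=None) -> LinearFit:
    """OLS fit of y on x; WLS with weights 1/u_y^2 when per-point
    uncertainties are supplied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise CalibrationError("at least 2 points are required")
    if len(np.unique(x)) < 2:
        raise CalibrationError("design is rank-deficient: all x values identical")

    if u_y is not None:
        u_y = np.asarray(u_y, dtype=float)
        if np.any(u_y <= 0):
            raise CalibrationError("per-point uncertainties must be positive")
        w = 1.0 / u_y**2
    else:
        w = np.ones(n)

    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    dof = n - 2
    if dof > 0:
        s2 = np.sum(w * resid**2) / dof
    else:
        s2 = 0.0
    # unweighted-scale residual s for OLS; for WLS, s2 is the scaled variance
    u_slope = math.sqrt(s2 / sxx)
    u_intercept = math.sqrt(s2 * (1.0 / sw + xbar**2 / sxx))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    s = math.sqrt(np.sum(resid**2) / dof) if dof > 0 else 0.0
    return LinearFit(slope=float(slope), intercept=float(intercept),
                     u_slope=float(u_slope), u_intercept=float(u_intercept),
                     r2=r2, residuals=resid, dof=dof, s=s, x=x, y=y,
                     weights=None if u_y is None else w)


def curvature_pvalue(x, residuals, y_scale: float = 1.0) -> float:
    """p-value of the quadratic term fitted to the residuals of a line fit.

    A small p-value indicates residual curvature, which for multi-field
    drift-tube data can signal field-dependent mobility or an effective
    drift length varying with voltage.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n = len(x)
    if n < 4:
        return 1.0
    # residuals at floating-point noise level carry no curvature information
    if np.max(np.abs(r)) < 1e-9 * abs(y_scale):
        return 1.0
    X = np.column_stack([np.ones(n), x, x**2])
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    fitted = X @ coef
    dof = n - 3
    s2 = float(np.sum((r - fitted) ** 2)) / dof if dof > 0 else 0.0
    if s2 == 0:
        return 1.0
    cov = s2 * np.linalg.inv(X.T @ X)
    tstat = coef[2] / math.sqrt(cov[2, 2])
    return float(2.0 * stats.t.sf(abs(tstat), df=dof))
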