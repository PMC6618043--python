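"""Drift-tube (and DMA) calibration workflows.

The multi-field experiment is the primary method: arrival times measured at
several drift voltages are regressed on 1/dV,

    t_A = (L^2/K0 * T0 p / (T p0)) * 1/dV + t0,

giving K0 from the slope (traceable to SI) and the time spent outside the
drift region, t0, from the intercept.  The single-field shortcut instead
calibrates t_A against gamma*CCS of reference ions,

    t_A = t_fix + beta * gamma * CCS,    gamma = sqrt(m_i/(m_g+m_i)) / z,

so a run at one field strength yields CCS values for unknowns.  A generic
linear voltage <-> 1/K0 law covers DMA voltage scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import gum
from .constants import CODATA_2014, DEFAULT_CONVENTION, M2_PER_CM2, ConstantsSet, ReferenceConvention
from .core import CcsResult, GasState, IonSpecies, MobilityResult, reduced_mass
from .errors import CalibrationError, DomainError
from .regression import LinearFit, curvature_pvalue, fit_line

#: significance level of the residual-curvature check on multi-field fits
CURVATURE_ALPHA = 0.05


@dataclass
class MultiFieldDataset:
    """Arrival times vs drift voltage, plus the drift length and gas state
    (with standard uncertainties) needed for a full uncertainty budget."""

    delta_v: np.ndarray       # V
    t_arrival: np.ndarray     # s
    drift_length: float       # m
    gas: GasState
    u_t: Optional[np.ndarray] = None  # s, per point
    u_L: float = 0.0          # m
    u_p: float = 0.0          # Pa
    u_T: float = 0.0          # K

    def __post_init__(self):
        self.delta_v = np.asarray(self.delta_v, dtype=float)
        self.t_arrival = np.asarray(self.t_arrival, dtype=float)
        if self.u_t is not None:
            self.u_t = np.asarray(self.u_t, dtype=float)
        if len(np.unique(self.delta_v)) < 2:
            raise CalibrationError("need at least 2 distinct drift voltages")
        if np.any(self.t_arrival <= 0):
            raise CalibrationError("arrival times must be positive")
        if self.drift_length <= 0:
            raise DomainError("drift length must be positive")


@dataclass
class SingleFieldCalibration:
    """Fitted single-field law t_A = t_fix + beta * (gamma * CCS)."""

    t_fix: float              # s
    beta: float               # s / (A^2 per gamma unit)
    u_t_fix: float
    u_beta: float
    gas: str
    fit: LinearFit = None

    def __post_init__(self):
        if self.beta <= 0:
            raise CalibrationError("beta must be positive for a physical calibration")


def fit_multifield(data: MultiFieldDataset,
                   convention: ReferenceConvention = DEFAULT_CONVENTION,
                   constants: ConstantsSet = CODATA_2014):
    """Regress t_A on 1/dV and derive K0 (cm^2 V^-1 s^-1) with its combined
    standard uncertainty.

    Returns (LinearFit, MobilityResult).  WLS is used when the dataset has
    per-point u(t_A); otherwise OLS (equal-variance assumption).  A quadratic
    t-test on the residuals flags curvature, which may indicate mobility
    varying with E/N over the voltage range.
    """
    x = 1.0 / data.delta_v
    fit = fit_line(x, data.t_arrival, u_y=data.u_t)
    p_curv = curvature_pvalue(x, fit.residuals,
                              y_scale=float(np.max(np.abs(data.t_arrival))))
    fit.diagnostics["curvature_pvalue"] = p_curv
    fit.diagnostics["curvature_flag"] = p_curv < CURVATURE_ALPHA
    if fit.diagnostics["curvature_flag"]:
        warnings.warn(
            "residual curvature detected in the multi-field fit "
            f"(p={p_curv:.3g}); mobility may depend on E/N over this range",
            stacklevel=2)

    cs = constants.with_convention(convention)
    gas = data.gas
    L = data.drift_length
    # slope = L^2 / K0 * (T0 p) / (T p0)  ->  K0 in SI, then cm^2/Vs
    k0_si = (L * L / fit.slope) * (cs.T0 * gas.pressure) / (gas.temperature * cs.p0)
    u_rel = gum.combined_u_k0(
        u_L_rel=data.u_L / L,
        u_T_rel=data.u_T / gas.temperature,
        u_p_rel=data.u_p / gas.pressure,
        u_slope_rel=fit.u_slope / abs(fit.slope) if fit.dof > 0 else 0.0,
    )
    mob = MobilityResult(K=float("nan"), K0=k0_si / M2_PER_CM2,
                         convention=convention, gas=gas, u_rel=u_rel,
                         constants=cs)
    # K at the median field for reference (K = K0 / (p/p0 * T0/T))
    mob.K = mob.K0 / ((gas.pressure / cs.p0) * (cs.T0 / gas.temperature))
    return fit, mob


def gamma_factor(ion: IonSpecies, m_g: float) -> float:
    """gamma = sqrt(m_i / (m_g + m_i)) / z (dimensionless)."""
    if ion.mass <= 0 or m_g <= 0:
        raise DomainError("masses must be positive")
    return np.sqrt(ion.mass / (m_g + ion.mass)) / ion.z


def fit_single_field(calibrants: Sequence[tuple], gas: str = "N2") -> SingleFieldCalibration:
    """Fit t_A = t_fix + beta * (gamma*CCS) over (t_A, gamma, ccs_ref) triples.

    At least 2 calibrants are required (3+ recommended, spanning the
    gamma*CCS range of the intended analytes).
    """
    if len(calibrants) < 2:
        raise CalibrationError("at least 2 calibrants are required")
    t_a = np.array([c[0] for c in calibrants], dtype=float)
    gc = np.array([c[1] * c[2] for c in calibrants], dtype=float)
    fit = fit_line(gc, t_a)
    return SingleFieldCalibration(t_fix=fit.intercept, beta=fit.slope,
                                  u_t_fix=fit.u_intercept, u_beta=fit.u_slope,
                                  gas=gas, fit=fit)


def apply_single_field(cal: SingleFieldCalibration, t_a: float, gamma: float,
                       level: float = 0.95,
                       calibration_gas: Optional[str] = None) -> CcsResult:
    """CCS = (t_A - t_fix) / (beta * gamma), with a prediction-band-derived
    relative uncertainty mapped back through the linear form."""
    if t_a <= cal.t_fix:
        raise CalibrationError(
            f"arrival time {t_a} <= t_fix {cal.t_fix}: unphysical (no transit time)")
    ccs = (t_a - cal.t_fix) / (cal.beta * gamma)
    gc = gamma * ccs
    flags = {}
    lo, hi = cal.fit.x_range
    if not lo <= gc <= hi:
        flags["extrapolated"] = True
    hw_t = float(cal.fit.prediction_halfwidth(gc, level))
    hw_ccs = hw_t / (cal.beta * gamma)
    u_rel = (hw_ccs / gum.coverage_factor(None, level)) / ccs if ccs > 0 else None
    flags["prediction_halfwidth_A2"] = hw_ccs
    flags["confidence_level"] = level
    return CcsResult(value=float(ccs), gas=cal.gas, method="DT", primary=False,
                     calibration_gas=calibration_gas, u_rel=u_rel, flags=flags)


def fit_linear_inverse_mobility(voltages, inverse_k0,
                                outlier_threshold: float = 3.0) -> LinearFit:
    """Generic linear law between applied voltage and 1/K0 (DMA calibration).

    Points whose studentized residual exceeds ``outlier_threshold`` are
    flagged in the fit diagnostics (never silently dropped).
    """
    fit = fit_line(np.asarray(voltages, dtype=float),
                   np.asarray(inverse_k0, dtype=float))
    sr = fit.studentized_residuals()
    outliers = np.nonzero(np.abs(sr) > outlier_threshold)[0]
    fit.diagnostics["studentized_residuals"] = sr
    fit.diagnostics["outlier_indices"] = outliers.tolist()
    return fit
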