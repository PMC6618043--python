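"""Traveling-wave calibration.

TWIMS cannot yield CCS from first principles; reference ions of known
drift-tube CCS are measured and an empirical law is fitted between the
reduced quantities

    CCS' = CCS * sqrt(mu) / z        (proportional to 1/K0)
    t'   = t_A - c * sqrt(m/z)       (mass-dependent transfer-time correction)

Four published fit forms are supported: a power law CCS' = A t'^N, its
log-linear version, a second-order polynomial, and a power law with a time
offset CCS' = A (t' - t0)^N.  Every result records that it is a secondary
(calibrated) value, the gas crossover when the reference values were
measured in a different gas, and the assumption that the instrument constant
relating CCS' to 1/K0 is the same for calibrants and analytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .core import CcsResult, GasState, IonSpecies, reduced_mass
from .errors import CalibrationError, DomainError
from .regression import LinearFit, fit_line


class TwimsForm(Enum):
    POWER = "power"            # CCS' = A * t'^N (fitted in log-log space)
    LOG_LINEAR = "loglin"      # ln CCS' = ln A + N ln t' (same law, stated linearized)
    POLY2 = "poly2"            # CCS' = A t'^2 + B t' + C
    POWER_T0 = "power-t0"      # CCS' = A (t' - t0)^N


#: minimum calibrant count per form = n_coefficients + 1
_MIN_POINTS = {TwimsForm.POWER: 3, TwimsForm.LOG_LINEAR: 3,
               TwimsForm.POLY2: 4, TwimsForm.POWER_T0: 4}


@dataclass(frozen=True)
class TwimsCalibrant:
    """A reference ion: measured arrival time plus its drift-tube CCS."""

    species: str
    mz: float
    z: int
    t_arrival: float          # s
    ccs_ref: float            # A^2
    u_ccs_ref: float = 0.0    # A^2
    ref_gas: str = "N2"       # gas in which ccs_ref was determined
    chem_class: str = ""

    def __post_init__(self):
        if self.mz <= 0 or self.z < 1 or self.t_arrival <= 0 or self.ccs_ref <= 0:
            raise DomainError("calibrant fields must be positive")

    @property
    def mass(self) -> float:
        return self.mz * self.z


@dataclass
class TwimsModel:
    """A fitted traveling-wave calibration law."""

    form: TwimsForm
    coefficients: dict
    c: float                   # transfer constant, s per sqrt(Da/charge)
    gas: GasState              # drift gas of the TWIMS cell
    ref_gas: str               # gas of the reference CCS values
    dof: int
    fit: Optional[LinearFit]   # underlying linear fit (log or poly space), if any
    t_prime_range: tuple
    settings_fingerprint: Optional[dict] = None
    residuals: np.ndarray = None
    s_log: float = 0.0         # residual std in ln CCS' space (power forms)
    assumptions: tuple = (
        "instrument constant R (effective-temperature factor) assumed equal "
        "for calibrants and analytes",
    )

    def predict_ccs_prime(self, t_prime):
        tp = np.asarray(t_prime, dtype=float)
        co = self.coefficients
        if self.form in (TwimsForm.POWER, TwimsForm.LOG_LINEAR):
            return co["A"] * tp ** co["N"]
        if self.form is TwimsForm.POLY2:
            return co["A"] * tp**2 + co["B"] * tp + co["C"]
        return co["A"] * (tp - co["t0"]) ** co["N"]


def ccs_prime(ccs: float, mu: float, z: int) -> float:
    """Reduced cross section CCS' = CCS * sqrt(mu) / z (mu in Da)."""
    if ccs <= 0 or mu <= 0 or z < 1:
        raise DomainError("inputs must be positive")
    return ccs * np.sqrt(mu) / z


def t_prime(t_a: float, c: float, mz: float) -> float:
    """Mass-corrected drift time t' = t_A - c * sqrt(m/z).

    The correction (typically ~100 us against drift times of several ms)
    removes m/z-dependent transfer-optics flight time."""
    if c < 0:
        raise DomainError("transfer constant c must be non-negative")
    tp = t_a - c * np.sqrt(mz)
    if tp <= 0:
        raise CalibrationError(
            f"t' = {tp:.3g} s <= 0: transfer correction exceeds the arrival time")
    return tp


def _prepare(calibrants: Sequence[TwimsCalibrant], c: float, gas: GasState):
    m_g = gas.molecular_mass()
    tp = np.array([t_prime(cal.t_arrival, c, cal.mz) for cal in calibrants])
    cp = np.array([ccs_prime(cal.ccs_ref, reduced_mass(cal.mass, m_g), cal.z)
                   for cal in calibrants])
    return tp, cp


def fit_twims(calibrants: Sequence[TwimsCalibrant], form: TwimsForm,
              gas: GasState, c: float = 0.0,
              settings_fingerprint: Optional[dict] = None) -> TwimsModel:
    """Fit the chosen calibration law to (t', CCS') of the calibrants.

    Power and log-linear forms are least squares in log-log space; the
    quadratic is linear least squares; the offset power law is nonlinear
    least squares with t0 initialized at 0 and bounded below min(t').
    """
    if len(calibrants) < _MIN_POINTS[form]:
        raise CalibrationError(
            f"{form.value} needs at least {_MIN_POINTS[form]} calibrants")
    ref_gases = {cal.ref_gas for cal in calibrants}
    if len(ref_gases) > 1:
        raise CalibrationError(f"mixed reference gases in calibrant set: {ref_gases}")
    tp, cp = _prepare(calibrants, c, gas)
    if len(np.unique(tp)) < len(tp):
        warnings.warn("duplicate t' values in calibrant set collapse the design",
                      stacklevel=2)

    fit = None
    s_log = 0.0
    if form in (TwimsForm.POWER, TwimsForm.LOG_LINEAR):
        fit = fit_line(np.log(tp), np.log(cp))
        coefficients = {"A": float(np.exp(fit.intercept)), "N": fit.slope}
        resid = np.log(cp) - fit.predict(np.log(tp))
        dof = fit.dof
        s_log = fit.s
    elif form is TwimsForm.POLY2:
        X = np.column_stack([tp**2, tp, np.ones_like(tp)])
        coef, *_ = np.linalg.lstsq(X, cp, rcond=None)
        resid = cp - X @ coef
        dof = len(tp) - 3
        coefficients = {"A": float(coef[0]), "B": float(coef[1]), "C": float(coef[2])}
    else:  # POWER_T0
        def law(t, a, n, t0):
            return a * (t - t0) ** n

        lower = [1e-300, -np.inf, -np.inf]
        upper = [np.inf, np.inf, 0.999 * float(np.min(tp))]
        p0 = [float(np.mean(cp / tp ** 0.5)), 0.5, 0.0]
        try:
            popt, _ = optimize.curve_fit(law, tp, cp, p0=p0,
                                         bounds=(lower, upper), maxfev=20000)
        except RuntimeError as exc:
            raise CalibrationError(f"power-t0 fit did not converge: {exc}") from exc
        resid = cp - law(tp, *popt)
        dof = len(tp) - 3
        coefficients = {"A": float(popt[0]), "N": float(popt[1]), "t0": float(popt[2])}
        s_log = float(np.sqrt(np.sum((np.log(cp) - np.log(law(tp, *popt))) ** 2)
                              / dof)) if dof > 0 else 0.0

    if dof < 1:
        raise CalibrationError("no degrees of freedom left after fitting")
    return TwimsModel(form=form, coefficients=coefficients, c=c, gas=gas,
                      ref_gas=next(iter(ref_gases)), dof=dof, fit=fit,
                      t_prime_range=(float(np.min(tp)), float(np.max(tp))),
                      settings_fingerprint=settings_fingerprint,
                      residuals=resid, s_log=s_log)


def apply_twims(model: TwimsModel, t_a: float, mz: float, z: int,
                gas: Optional[GasState] = None, level: float = 0.95,
                settings_fingerprint: Optional[dict] = None,
                strict_settings: bool = False) -> CcsResult:
    """Calibrated CCS of an unknown ion from its arrival time.

    Inverts CCS' = CCS sqrt(mu)/z after evaluating the fitted law at t'.
    The prediction band of the underlying fit gives the uncertainty; results
    outside the calibrant t' range are flagged as extrapolated.
    """
    gas = gas if gas is not None else model.gas
    if model.settings_fingerprint is not None and settings_fingerprint is not None:
        if settings_fingerprint != model.settings_fingerprint:
            msg = ("instrument settings fingerprint differs between calibration "
                   "and query; traveling-wave calibrations are only valid at "
                   "identical settings")
            if strict_settings:
                raise CalibrationError(msg)
            warnings.warn(msg, stacklevel=2)
    tp = t_prime(t_a, model.c, mz)
    cp = float(model.predict_ccs_prime(tp))
    mu = reduced_mass(mz * z, gas.molecular_mass())
    ccs = cp * z / np.sqrt(mu)
    flags = {"assumptions": list(model.assumptions)}
    lo, hi = model.t_prime_range
    if not lo <= tp <= hi:
        flags["extrapolated"] = True

    u_rel = None
    if model.form in (TwimsForm.POWER, TwimsForm.LOG_LINEAR) and model.fit is not None:
        hw_log = float(model.fit.prediction_halfwidth(np.log(tp), level))
        # symmetric band in log space ~ relative band in linear space
        flags["prediction_halfwidth_rel"] = float(np.expm1(hw_log))
        u_rel = hw_log / stats.t.ppf(0.5 + level / 2.0, df=model.dof)
    elif model.residuals is not None and model.dof > 0:
        s = float(np.sqrt(np.sum(model.residuals**2) / model.dof))
        n = len(model.residuals)
        t = stats.t.ppf(0.5 + level / 2.0, df=model.dof)
        hw = t * s * np.sqrt(1.0 + 1.0 / n)
        flags["prediction_halfwidth_rel"] = hw / cp
        u_rel = (s * np.sqrt(1.0 + 1.0 / n)) / cp

    return CcsResult(value=float(ccs), gas=gas.label, method="TW", primary=False,
                     calibration_gas=model.ref_gas, temperature=gas.temperature,
                     u_rel=u_rel, flags=flags)


def calibrant_match_report(calibrants: Sequence[TwimsCalibrant],
                           analytes: Sequence[IonSpecies],
                           drift_gas: str = "N2",
                           analyte_classes: Optional[Sequence[str]] = None) -> list:
    """Advisory checks on calibrant/analyte matching.

    Calibrated traveling-wave data agree better with drift-tube data when the
    charge state and chemical class of the calibrants match the analytes, and
    when the reference values were measured in the drift gas actually used.
    Returns a list of finding dicts; empty means no concerns.
    """
    findings = []
    cal_charges = {c.z for c in calibrants}
    for ion in analytes:
        if cal_charges and min(abs(ion.z - cz) for cz in cal_charges) > 2:
            findings.append({
                "rule": "charge-mismatch",
                "detail": f"analyte charge {ion.z} far from calibrant charges "
                          f"{sorted(cal_charges)}",
            })
    if analyte_classes:
        cal_classes = {c.chem_class for c in calibrants if c.chem_class}
        for cls in analyte_classes:
            if cal_classes and cls not in cal_classes:
                findings.append({
                    "rule": "class-mismatch",
                    "detail": f"analyte class {cls!r} not among calibrant classes "
                              f"{sorted(cal_classes)}",
                })
    ref_gases = {c.ref_gas for c in calibrants}
    for rg in ref_gases:
        if rg != drift_gas:
            findings.append({
                "rule": "gas-crossover",
                "detail": f"reference CCS measured in {rg} but drift gas is "
                          f"{drift_gas}; report values as {drift_gas}->{rg} and "
                          f"prefer {drift_gas}-referenced calibrants",
                "notation": f"^TW^CCS_{drift_gas}->{rg}",
            })
    return findings


def reject_calculated_calibrants(rows: Sequence[dict]) -> Sequence[dict]:
    """Drop rows whose reference CCS is theoretical/calculated.

    Calculated cross sections are not traceable to the SI and must not be
    used to calibrate an instrument; offending rows raise."""
    for row in rows:
        if str(row.get("source", "")).lower() in ("calculated", "theoretical"):
            raise CalibrationError(
                f"calibrant {row.get('species')!r} has a calculated reference CCS; "
                "calculated values are not traceable to the SI and cannot calibrate "
                "a measurement")
    return rows
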