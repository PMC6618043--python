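"""Trapped ion mobility (TIMS) model and calibration.

In a TIMS analyzer ions are held against a gas stream by an axial electric
field that rises over the entrance ramp and is flat over the plateau; the
plateau height is scanned down in time, releasing ions in order of mobility:

    E(z, t) = s(z) * (E0 - beta * t)   for z <  z0
    E(z, t) =        (E0 - beta * t)   for z >= z0

The primary measurand is the scan number / elution voltage Ve.  Two
calibration routes are implemented: the scan-rate method (total time is
linear in ramp time at fixed ramp voltage, giving t0 and Ve) and the
first-order law K0 = a + b/Ve fitted on calibrant ions.  The fitted a, b are
only valid for the exact instrument settings (scan rate, range, pressures),
which is enforced through a settings fingerprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .constants import CODATA_2014, DEFAULT_CONVENTION, ConstantsSet, ReferenceConvention
from .core import CcsResult, GasState, IonSpecies, MobilityResult, ccs_from_k0
from .errors import CalibrationError, DomainError
from .regression import LinearFit, fit_line


@dataclass
class TimsFieldProfile:
    """Axial field profile: plateau height E0 scanned down at rate beta_scan,
    with ramp shape s(z) on [0, z0] (s(z0) = 1; linear by default)."""

    E0: float                  # V/m
    beta_scan: float           # V/m per s
    z0: float                  # m
    s_profile: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.z0 <= 0:
            raise DomainError("z0 must be positive")

    def s(self, z: float) -> float:
        if self.s_profile is not None:
            return self.s_profile(z)
        return z / self.z0


def tims_field_at(profile: TimsFieldProfile, z: float, t: float) -> float:
    """Field strength (V/m) at axial position z and time t: piecewise ramp /
    plateau, continuous at z = z0."""
    if z < 0:
        raise DomainError("z must be non-negative")
    plateau = profile.E0 - profile.beta_scan * t
    if z >= profile.z0:
        return plateau
    return profile.s(z) * plateau


@dataclass
class TimsScan:
    """One TIMS acquisition: voltage ramp settings, timing and pressures."""

    vramp_start: float        # V
    vramp_end: float          # V
    v_out: float              # V
    t_ramp: float             # s
    t_trap: float = 0.0       # s
    p1_mbar: Optional[float] = None
    p2_mbar: Optional[float] = None
    gas_velocity: Optional[float] = None  # m/s

    @property
    def vramp_span(self) -> float:
        return abs(self.vramp_end - self.vramp_start)

    def contains_ve(self, ve: float) -> bool:
        lo, hi = sorted((self.vramp_start, self.vramp_end))
        return lo <= ve <= hi

    def fingerprint(self) -> dict:
        return {
            "vramp_start": self.vramp_start,
            "vramp_end": self.vramp_end,
            "t_ramp": self.t_ramp,
            "p1_mbar": self.p1_mbar,
            "p2_mbar": self.p2_mbar,
        }


@dataclass
class TimsCalibrationModel:
    """First-order law K0 = a + b / Ve with its validity fingerprint."""

    a: float
    b: float
    u_a: float
    u_b: float
    fingerprint: Optional[dict]
    fit: LinearFit
    ve_range: tuple
    valid: bool = True
    assumptions: tuple = ("an average post-IMS flight time is assumed",)

    def k0_at(self, ve: float) -> float:
        return self.a + self.b / ve

    def invalidate(self, reason: str = "") -> None:
        self.valid = False
        self._invalid_reason = reason


def fit_scan_rate_method(t_ramp, t_total, vramp: float):
    """Scan-rate calibration: t_total = t0 + (Ve / Vramp) * t_ramp at fixed
    ramp voltage.  Returns (t0, Ve, LinearFit).

    Varying Vramp across the inputs is a protocol error; pass each Vramp
    group separately.  A zero slope means Ve = 0 and is flagged unphysical.
    """
    t_ramp = np.asarray(t_ramp, dtype=float)
    t_total = np.asarray(t_total, dtype=float)
    if np.ndim(vramp) != 0:
        vr = np.asarray(vramp, dtype=float)
        if len(np.unique(vr)) > 1:
            raise CalibrationError(
                "Vramp varies across scans; the scan-rate method requires a "
                "fixed ramp voltage per fit")
        vramp = float(vr[0])
    if len(np.unique(t_ramp)) < 2:
        raise CalibrationError("need at least 2 distinct ramp times")
    fit = fit_line(t_ramp, t_total)
    ve = fit.slope * vramp
    if ve <= 0:
        raise CalibrationError(
            f"fitted elution voltage {ve:.3g} V is unphysical (slope <= 0)")
    return fit.intercept, ve, fit


def fit_tims_first_order(calibrants: Sequence[tuple],
                         fingerprint: Optional[dict] = None,
                         calibrant_fingerprints: Optional[Sequence[dict]] = None
                         ) -> TimsCalibrationModel:
    """OLS of reference K0 on 1/Ve over (Ve, K0_ref) calibrant pairs.

    All calibrants must share the settings fingerprint when one is given.
    """
    if len(calibrants) < 2:
        raise CalibrationError("at least 2 calibrants are required")
    if calibrant_fingerprints is not None:
        for fp in calibrant_fingerprints:
            if fp != fingerprint:
                raise CalibrationError(
                    "calibrants acquired at different TIMS settings cannot share "
                    "a first-order calibration")
    ve = np.array([c[0] for c in calibrants], dtype=float)
    k0 = np.array([c[1] for c in calibrants], dtype=float)
    if np.any(ve <= 0) or np.any(k0 <= 0):
        raise CalibrationError("elution voltages and mobilities must be positive")
    fit = fit_line(1.0 / ve, k0)
    model = TimsCalibrationModel(a=fit.intercept, b=fit.slope,
                                 u_a=fit.u_intercept, u_b=fit.u_slope,
                                 fingerprint=fingerprint, fit=fit,
                                 ve_range=(float(np.min(ve)), float(np.max(ve))))
    # monotonicity on the calibrated branch: K0 must vary consistently with Ve
    if fit.slope == 0:
        warnings.warn("flat first-order calibration (b = 0): K0 independent of Ve",
                      stacklevel=2)
    return model


def apply_tims(model: TimsCalibrationModel, ve: float, ion: IonSpecies,
               gas: GasState, level: float = 0.95,
               query_fingerprint: Optional[dict] = None,
               convention: ReferenceConvention = DEFAULT_CONVENTION,
               constants: ConstantsSet = CODATA_2014):
    """K0 = a + b/Ve for an analyte, then CCS through the low-field equation.

    Returns (MobilityResult, CcsResult), both tagged as calibrated TIMS
    values.  A fingerprint mismatch between model and query raises; Ve
    outside the calibrant range is flagged as extrapolation.
    """
    if not model.valid:
        raise CalibrationError("calibration model has been invalidated "
                               f"({getattr(model, '_invalid_reason', 'settings changed')})")
    if model.fingerprint is not None and query_fingerprint is not None \
            and query_fingerprint != model.fingerprint:
        raise CalibrationError(
            "TIMS settings fingerprint mismatch: first-order coefficients are "
            "only valid for the exact settings used to determine them")
    if ve <= 0:
        raise DomainError("elution voltage must be positive")
    k0 = model.k0_at(ve)
    if k0 <= 0:
        raise CalibrationError(f"calibrated K0 = {k0:.3g} is unphysical at Ve = {ve}")
    flags = {"assumptions": list(model.assumptions)}
    lo, hi = model.ve_range
    if not lo <= ve <= hi:
        flags["extrapolated"] = True
    hw = float(model.fit.prediction_halfwidth(1.0 / ve, level))
    u_rel = None
    if model.fit.dof > 0:
        u_rel = (hw / stats.t.ppf(0.5 + level / 2.0, df=model.fit.dof)) / k0
    mob = MobilityResult(K=k0 / ((gas.pressure / constants.with_convention(convention).p0)
                                 * (constants.with_convention(convention).T0 / gas.temperature)),
                         K0=k0, convention=convention, gas=gas, u_rel=u_rel,
                         constants=constants.with_convention(convention))
    ccs = ccs_from_k0(k0, gas, ion, convention=convention, constants=constants,
                      method="TIMS", primary=False)
    ccs.u_rel = u_rel
    ccs.calibration_gas = gas.label  # calibrant K0 values measured in the same gas
    ccs.flags.update(flags)
    ccs.flags["prediction_halfwidth_K0"] = hw
    return mob, ccs
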