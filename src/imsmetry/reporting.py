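"""Arrival-time distributions, centroids, CCS distributions, notation and
report compliance.

The arrival time distribution (ATD) is the instrument's raw output: counts
versus the time at which ions reach the detector (or versus scan number /
elution voltage for scanning analyzers — the axis kind is recorded, and the
axis must be labeled for what was actually measured).  A single peak is
summarized by a centroid (apex, Gaussian-fit mean, or intensity-weighted
mean).  A calibrated ATD can be transformed into an *apparent* CCS
distribution with Jacobian-corrected intensities, keeping the inverse
parameters so the transform is fully reversible.

The notation formatter renders the community convention: method superscript
(with ",1ry" for primary values), CCS, gas subscript (gas1->gas2 for
calibrated crossover) and an optional temperature suffix, e.g.
^DT,1ry^CCS_He,298.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .core import CcsResult, GasState, IonSpecies
from .errors import DomainError, FormattingError, NoPeakError, ValidationError

AXIS_KINDS = ("arrival_time", "scan_number", "elution_voltage", "ccs")


@dataclass
class ArrivalTimeDistribution:
    """Counts vs a strictly monotone axis (arrival time, scan number, ...)."""

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "arrival_time"
    axis_unit: str = "s"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape or self.axis.ndim != 1:
            raise DomainError("axis and intensity must be matching 1-D arrays")
        if self.axis_kind not in AXIS_KINDS:
            raise DomainError(
                f"axis kind {self.axis_kind!r} not in {AXIS_KINDS}; label the "
                "axis for what was measured (e.g. 'arrival_time', not 'drift time')")
        if np.any(np.diff(self.axis) <= 0):
            raise DomainError("axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise DomainError("intensities must be non-negative")

    def bin_widths(self) -> np.ndarray:
        """Per-sample bin widths with edges midway between samples."""
        edges = self.bin_edges()
        return np.diff(edges)

    def bin_edges(self) -> np.ndarray:
        x = self.axis
        inner = 0.5 * (x[:-1] + x[1:])
        first = x[0] - (inner[0] - x[0])
        last = x[-1] + (x[-1] - inner[-1])
        return np.concatenate([[first], inner, [last]])

    def total_intensity(self) -> float:
        """Bin-integrated intensity (conserved under axis transforms)."""
        return float(np.sum(self.intensity * self.bin_widths()))


@dataclass
class PeakDescriptor:
    """Summary of one peak: centroid (with method tag), FWHM and area."""

    centroid: float
    method: str                       # apex | gaussian_fit | weighted_mean
    fwhm: Optional[float] = None
    area: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def find_centroid(atd: ArrivalTimeDistribution, method: str = "apex",
                  window: Optional[tuple] = None) -> PeakDescriptor:
    """Peak centroid in the (optional) axis window.

    ``apex`` takes the axis value of maximum intensity (ties resolved toward
    the lower axis value and flagged); ``gaussian_fit`` fits a single
    Gaussian by nonlinear least squares; ``weighted_mean`` is the
    intensity-weighted mean over the window.
    """
    x, y = atd.axis, atd.intensity
    if window is not None:
        sel = (x >= window[0]) & (x <= window[1])
        x, y = x[sel], y[sel]
    if len(x) == 0 or np.all(y == y[0] if len(y) else True):
        raise NoPeakError("window is empty or flat: no peak to locate")
    ymax = float(np.max(y))
    if ymax <= 0:
        raise NoPeakError("no positive intensity in window")

    diagnostics = {}
    apex_candidates = np.nonzero(y == ymax)[0]
    apex_idx = int(apex_candidates[0])
    if len(apex_candidates) > 1:
        diagnostics["apex_tie"] = True
        diagnostics["tie_axis_values"] = x[apex_candidates].tolist()

    # FWHM by linear interpolation of the half-max crossings around the apex
    half = ymax / 2.0
    fwhm = None
    above = y >= half
    if above.any() and not above.all():
        idx = np.nonzero(above)[0]
        lo_i, hi_i = idx[0], idx[-1]
        lo = x[lo_i] if lo_i == 0 else np.interp(half, [y[lo_i - 1], y[lo_i]],
                                                 [x[lo_i - 1], x[lo_i]])
        hi = x[hi_i] if hi_i == len(x) - 1 else np.interp(
            half, [y[hi_i + 1], y[hi_i]], [x[hi_i + 1], x[hi_i]])
        fwhm = float(hi - lo)
    area = float(np.trapezoid(y, x))

    if method == "apex":
        centroid = float(x[apex_idx])
    elif method == "weighted_mean":
        centroid = float(np.sum(x * y) / np.sum(y))
    elif method == "gaussian_fit":
        sigma0 = fwhm / 2.3548 if fwhm else (x[-1] - x[0]) / 6.0
        try:
            popt, pcov = optimize.curve_fit(
                _gauss, x, y, p0=[ymax, x[apex_idx], max(sigma0, 1e-12)],
                maxfev=10000)
        except RuntimeError as exc:
            raise NoPeakError(f"Gaussian fit did not converge: {exc}") from exc
        centroid = float(popt[1])
        diagnostics["gaussian_params"] = {"amp": float(popt[0]),
                                          "mu": float(popt[1]),
                                          "sigma": float(abs(popt[2]))}
        diagnostics["gaussian_fwhm"] = 2.3548 * float(abs(popt[2]))
    else:
        raise DomainError(f"unknown centroid method {method!r}")
    if not (x[0] <= centroid <= x[-1]):
        raise NoPeakError(f"centroid {centroid:g} outside the window support")
    return PeakDescriptor(centroid=centroid, method=method, fwhm=fwhm,
                          area=area, diagnostics=diagnostics)


def atd_to_ccsd(atd: ArrivalTimeDistribution,
                transform: Callable[[np.ndarray], np.ndarray],
                charge_states: Sequence[int] = (1,),
                label: str = "apparent CCSD") -> ArrivalTimeDistribution:
    """Transform an ATD into an apparent CCS distribution.

    ``transform`` maps axis values to CCS (monotone over the axis range).
    Intensities are corrected with the discrete Jacobian (bin width ratio),
    which conserves the bin-integrated intensity exactly and makes the
    transform invertible.  Refuses windows with more than one declared charge
    state, where a single-axis CCS assignment is meaningless.
    """
    if len(set(charge_states)) != 1:
        raise DomainError(
            "apparent CCSD is undefined when ions of different charges coexist "
            "in the extraction window")
    new_axis = np.asarray(transform(atd.axis), dtype=float)
    diffs = np.diff(new_axis)
    if np.all(diffs < 0):
        new_axis = new_axis[::-1]
        old_widths = atd.bin_widths()[::-1]
        intensity = atd.intensity[::-1]
        orig_axis = atd.axis[::-1]
    elif np.all(diffs > 0):
        old_widths = atd.bin_widths()
        intensity = atd.intensity
        orig_axis = atd.axis
    else:
        raise DomainError("transform is not monotone over the axis range")

    out = ArrivalTimeDistribution(axis=new_axis, intensity=intensity,
                                  axis_kind="ccs", axis_unit="A^2",
                                  metadata=dict(atd.metadata))
    new_widths = out.bin_widths()
    out.intensity = intensity * old_widths / new_widths
    out.metadata.update({
        "label": label,
        "source_axis_kind": atd.axis_kind,
        "source_axis_unit": atd.axis_unit,
        # full inverse parameters for traceability
        "inverse_axis": orig_axis.tolist(),
        "inverse_intensity": intensity.tolist(),
    })
    return out


def ccsd_to_atd(ccsd: ArrivalTimeDistribution) -> ArrivalTimeDistribution:
    """Invert :func:`atd_to_ccsd` using the stored inverse parameters."""
    meta = ccsd.metadata
    if "inverse_axis" not in meta:
        raise DomainError("distribution carries no inverse parameters")
    return ArrivalTimeDistribution(
        axis=np.asarray(meta["inverse_axis"], dtype=float),
        intensity=np.asarray(meta["inverse_intensity"], dtype=float),
        axis_kind=meta.get("source_axis_kind", "arrival_time"),
        axis_unit=meta.get("source_axis_unit", "s"))


def format_notation(ccs: CcsResult, include_temperature: bool = False) -> str:
    """Community notation for a CCS value, e.g. ^DT,1ry^CCS_He,298 or
    ^TW^CCS_N2->He for a calibrated crossover value."""
    sup = ccs.method + (",1ry" if ccs.primary else "")
    if not ccs.primary and ccs.method in ("TW", "TIMS", "DMA") \
            and ccs.calibration_gas is None:
        raise FormattingError(
            "secondary value lacks calibration-gas provenance; record the gas "
            "in which the reference values were determined")
    gas = ccs.gas
    if ccs.calibration_gas and ccs.calibration_gas != ccs.gas:
        gas = f"{ccs.gas}->{ccs.calibration_gas}"
    sub = gas
    if include_temperature:
        if ccs.temperature is None:
            raise FormattingError("no temperature recorded on this result")
        sub += f",{ccs.temperature:g}"
    return f"^{sup}^CCS_{sub}"


# --- report compliance -----------------------------------------------------

#: required metadata fields per platform, reconstructed from the narrative
#: reporting recommendations (the canonical table is a figure); each entry is
#: (field name, justification)
REQUIRED_FIELDS = {
    "common": [
        ("sample_preparation", "sample and ion preparation determine which ion "
                               "population is measured"),
        ("ionization", "source conditions influence adducts/charge isomers"),
        ("gas_identity", "the buffer gas is part of the measurand definition"),
        ("gas_purity", "trace contaminants shift mobility and reduced mass"),
        ("temperature", "gas temperature is part of the measurand definition"),
        ("instrument_model", "instrument geometry/settings context"),
        ("mz_selection_range", "transmitted m/z range defines the ion population"),
        ("mz_extraction_range", "processing window defines isotopologue scope"),
    ],
    "dtims": [
        ("pressure", "drift gas pressure enters K0 directly"),
        ("drift_length", "E = dV/L; L enters K0 as L^2"),
        ("drift_voltages", "voltages define the fields used"),
        ("e_over_n", "report E/N (or E, p, T) even in the low-field limit"),
    ],
    "twims": [
        ("wave_height", "traveling-wave amplitude defines the effective field"),
        ("wave_velocity", "wave speed defines the separation conditions"),
        ("pressures", "He and N2 cell pressures or flow settings"),
        ("calibrant_list", "secondary method: calibrants and their reference "
                           "values must be stated"),
    ],
    "tims": [
        ("vramp_range", "scanned voltage range defines the mobility window"),
        ("t_ramp", "scan rate determines the calibration validity"),
        ("p1_mbar", "entrance pressure sets the gas velocity"),
        ("p2_mbar", "exit pressure sets the gas velocity"),
        ("calibrant_list", "secondary method: calibrants must be stated"),
    ],
    "dma": [
        ("geometry", "classification-region dimensions or commercial model"),
        ("sheath_flow", "sheath flow rate sets the mobility scale"),
        ("voltage_range", "scanned voltage range"),
    ],
    "faims": [
        ("gap_width", "fields E_D, E_C follow from voltages / gap width"),
        ("waveform_frequency", "first key waveform metric"),
        ("dispersion_voltage_zero_to_peak", "DV must be the zero-to-peak "
                                            "amplitude, never peak-to-peak"),
        ("waveform_profile", "asymmetric profile (analytic or sampled) or moments"),
        ("cv_range_or_values", "compensation-voltage program"),
        ("pressure", "separation parameters scale as inverse pressure squared"),
    ],
}

ISOTOPOLOGUE_SCOPES = ("monoisotopic", "average", "most_probable")


@dataclass
class MeasurandRecord:
    """Free-form experiment metadata checked against the per-platform rules."""

    fields: dict

    def get(self, key):
        return self.fields.get(key)


def validate_report(record: MeasurandRecord, platform: str) -> dict:
    """Check a metadata record against the platform's required-field list.

    Returns {"platform", "passed", "findings": [{field, reason}, ...]}.
    Adding fields can only remove findings, never add them.  An empty record
    never passes.
    """
    platform = platform.lower()
    if platform not in REQUIRED_FIELDS or platform == "common":
        raise ValidationError(f"unknown platform {platform!r}")
    findings = []
    for name, reason in REQUIRED_FIELDS["common"] + REQUIRED_FIELDS[platform]:
        value = record.get(name)
        if value is None or value == "":
            findings.append({"field": name, "reason": f"missing: {reason}"})
    scope = record.get("isotopologue_scope")
    if scope is not None and scope not in ISOTOPOLOGUE_SCOPES:
        findings.append({"field": "isotopologue_scope",
                         "reason": f"must be one of {ISOTOPOLOGUE_SCOPES}"})
    if platform == "faims" and record.get("dispersion_voltage_peak_to_peak") is not None:
        findings.append({
            "field": "dispersion_voltage_peak_to_peak",
            "reason": "state the zero-to-peak amplitude of the waveform, not "
                      "the peak-to-peak amplitude",
        })
    return {"platform": platform, "passed": not findings, "findings": findings,
            "ruleset": "reconstructed-from-narrative-v1"}
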