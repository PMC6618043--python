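"""Ground-truth generators for every calibration and uncertainty routine.

Each generator simulates the measurement chain of one platform from known
truth parameters: noise (relative Gaussian, default 0.5 % — the typical
inter-instrument dispersion of drift-tube cross sections) is applied to the
*measured* quantities (times, voltages) only, never to the truth, and every
generator returns a machine-readable truth record alongside the data.
Identical seeds give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import CODATA_2014, DEFAULT_CONVENTION, M2_PER_CM2, ConstantsSet, ReferenceConvention
from .core import GasState, IonSpecies, k0_from_ccs, reduced_mass
from .dtims import MultiFieldDataset, gamma_factor
from .errors import DomainError
from .faims import AlphaFunction, AsymmetricWaveform, FaimsCurve, forward_curve
from .reporting import ArrivalTimeDistribution
from .twims import TwimsCalibrant, TwimsForm, ccs_prime

#: default relative Gaussian noise on measured quantities
DEFAULT_NOISE = 0.005


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise DomainError("a seed is mandatory for reproducible fixtures")
    return np.random.default_rng(seed)


def make_multifield(true_k0: float, drift_length: float, gas: GasState,
                    t0: float, delta_v, seed: int,
                    noise_rel: float = DEFAULT_NOISE,
                    convention: ReferenceConvention = DEFAULT_CONVENTION,
                    constants: ConstantsSet = CODATA_2014):
    """Multi-field drift-tube dataset from a known reduced mobility.

    ``true_k0`` in cm^2 V^-1 s^-1; arrival times follow
    t_A = slope/dV + t0 with slope = L^2/K0 * T0 p / (T p0), plus relative
    Gaussian noise on t_A.  Returns (MultiFieldDataset, truth dict).
    """
    rng = _rng(seed)
    cs = constants.with_convention(convention)
    delta_v = np.asarray(delta_v, dtype=float)
    k0_si = true_k0 * M2_PER_CM2
    slope = (drift_length**2 / k0_si) * (cs.T0 * gas.pressure) / (gas.temperature * cs.p0)
    t_clean = slope / delta_v + t0
    t_meas = t_clean * (1.0 + noise_rel * rng.standard_normal(len(delta_v)))
    data = MultiFieldDataset(delta_v=delta_v, t_arrival=t_meas,
                             drift_length=drift_length, gas=gas)
    truth = {"K0": true_k0, "slope": slope, "t0": t0, "noise_rel": noise_rel,
             "seed": seed, "convention": convention.label}
    return data, truth


def make_single_field_set(t_fix: float, beta: float, gas_mass: float,
                          species: Sequence[tuple], seed: int,
                          noise_rel: float = DEFAULT_NOISE):
    """Single-field calibrant set from known t_fix and beta.

    ``species`` is a sequence of (mass_da, z, true_ccs).  Returns
    (list of (t_A, gamma, ccs) triples, truth dict)."""
    rng = _rng(seed)
    rows = []
    for mass, z, ccs in species:
        gamma = gamma_factor(IonSpecies(mass=mass, z=z), gas_mass)
        t_clean = t_fix + beta * gamma * ccs
        t_meas = t_clean * (1.0 + noise_rel * rng.standard_normal())
        rows.append((float(t_meas), float(gamma), float(ccs)))
    truth = {"t_fix": t_fix, "beta": beta, "noise_rel": noise_rel, "seed": seed}
    return rows, truth


def make_twims_set(form: TwimsForm, coefficients: dict, gas: GasState,
                   species: Sequence[dict], seed: int,
                   noise_rel: float = DEFAULT_NOISE, c: float = 0.0):
    """Traveling-wave calibrant set generated by inverting the chosen law.

    ``species`` rows need keys mz, z, ccs (A^2) and may carry chem_class and
    ref_gas.  For the power law t' = (CCS'/A)^(1/N); the offset form adds t0.
    Noise goes on the arrival time.  Returns (list of TwimsCalibrant, truth).
    """
    rng = _rng(seed)
    m_g = gas.molecular_mass()
    cals = []
    for row in species:
        mu = reduced_mass(row["mz"] * row["z"], m_g)
        cp = ccs_prime(row["ccs"], mu, row["z"])
        if form in (TwimsForm.POWER, TwimsForm.LOG_LINEAR):
            tp = (cp / coefficients["A"]) ** (1.0 / coefficients["N"])
        elif form is TwimsForm.POWER_T0:
            tp = (cp / coefficients["A"]) ** (1.0 / coefficients["N"]) \
                + coefficients["t0"]
        else:  # POLY2: solve A t^2 + B t + C = cp for the positive root
            a, b, cc = coefficients["A"], coefficients["B"], coefficients["C"] - cp
            disc = b * b - 4 * a * cc
            if disc < 0:
                raise DomainError("quadratic law cannot produce this CCS'")
            # numerically stable form (a may be tiny for near-linear laws)
            q = -0.5 * (b + np.copysign(np.sqrt(disc), b))
            roots = [r for r in (q / a if a != 0 else np.inf, cc / q) if r > 0]
            if not roots:
                raise DomainError("quadratic law has no positive drift-time root")
            tp = min(roots)
        t_a = tp + c * np.sqrt(row["mz"])
        t_meas = t_a * (1.0 + noise_rel * rng.standard_normal())
        cals.append(TwimsCalibrant(
            species=row.get("species", f"cal{len(cals)}"), mz=row["mz"],
            z=row["z"], t_arrival=float(t_meas), ccs_ref=row["ccs"],
            ref_gas=row.get("ref_gas", gas.label),
            chem_class=row.get("chem_class", "")))
    truth = {"form": form.value, "coefficients": dict(coefficients),
             "c": c, "noise_rel": noise_rel, "seed": seed}
    return cals, truth


def make_tims_calibrants(a: float, b: float, k0_values, seed: int,
                         noise_rel: float = DEFAULT_NOISE,
                         fingerprint: Optional[dict] = None):
    """First-order TIMS calibrant set from known a, b: Ve = b/(K0 - a),
    with noise on the measured elution voltage.  Returns (pairs, truth)."""
    rng = _rng(seed)
    k0_values = np.asarray(k0_values, dtype=float)
    if np.any(k0_values <= a):
        raise DomainError("all K0 must exceed the intercept a for positive Ve")
    ve_clean = b / (k0_values - a)
    ve_meas = ve_clean * (1.0 + noise_rel * rng.standard_normal(len(k0_values)))
    pairs = [(float(v), float(k)) for v, k in zip(ve_meas, k0_values)]
    truth = {"a": a, "b": b, "noise_rel": noise_rel, "seed": seed,
             "fingerprint": fingerprint}
    return pairs, truth


def make_tims_scan_rate(t0: float, ve: float, vramp: float, t_ramps,
                        seed: int, noise_rel: float = DEFAULT_NOISE):
    """Scan-rate-method dataset: t_total = t0 + (Ve/Vramp) t_ramp + noise."""
    rng = _rng(seed)
    t_ramps = np.asarray(t_ramps, dtype=float)
    t_tot = t0 + (ve / vramp) * t_ramps
    t_meas = t_tot * (1.0 + noise_rel * rng.standard_normal(len(t_ramps)))
    truth = {"t0": t0, "Ve": ve, "Vramp": vramp, "noise_rel": noise_rel,
             "seed": seed}
    return t_ramps, t_meas, truth


def make_faims_curve(coefficients: tuple, wf: AsymmetricWaveform, ed_td,
                     seed: int, noise_rel: float = 0.0, gas: str = "N2"):
    """E_C(E_D) curve (Td) generated through the forward transmission model
    from known alpha coefficients; optional relative noise on E_C.
    Returns (FaimsCurve, truth dict with the AlphaFunction)."""
    rng = _rng(seed)
    alpha = AlphaFunction(coefficients=tuple(coefficients))
    curve = forward_curve(alpha, wf, ed_td, gas=gas)
    if noise_rel > 0:
        scale = np.maximum(np.abs(curve.e_c), np.max(np.abs(curve.e_c)) * 0.1)
        curve.e_c = curve.e_c + noise_rel * scale * rng.standard_normal(len(curve.e_c))
    truth = {"coefficients": tuple(coefficients), "noise_rel": noise_rel,
             "seed": seed, "alpha": alpha}
    return curve, truth


def make_atd(centroid: float, fwhm: float, n_points: int = 400,
             seed: int = 0, amplitude: float = 1000.0,
             tail_tau: float = 0.0, second_peak: Optional[tuple] = None,
             noise_rel: float = 0.0, axis_span: float = 4.0):
    """Synthetic arrival-time distribution: a Gaussian peak, optionally with
    an exponential tail (convolution) and/or a second conformer peak given as
    (centroid, fwhm, amplitude).  Returns (ArrivalTimeDistribution, truth).

    For protein-like peaks the width regime is FWHM ~ 10 % of the centroid.
    """
    rng = _rng(seed)
    sigma = fwhm / 2.3548
    lo = centroid - axis_span * fwhm
    hi = centroid + axis_span * fwhm
    if second_peak is not None:
        lo = min(lo, second_peak[0] - axis_span * second_peak[1])
        hi = max(hi, second_peak[0] + axis_span * second_peak[1])
    x = np.linspace(max(lo, 1e-9), hi, n_points)
    y = amplitude * np.exp(-0.5 * ((x - centroid) / sigma) ** 2)
    if tail_tau > 0:
        dx = x[1] - x[0]
        kernel_x = np.arange(0, 10 * tail_tau, dx)
        kernel = np.exp(-kernel_x / tail_tau)
        kernel /= kernel.sum()
        y = np.convolve(y, kernel, mode="full")[: len(x)]
    if second_peak is not None:
        c2, w2, a2 = second_peak
        y = y + a2 * np.exp(-0.5 * ((x - c2) / (w2 / 2.3548)) ** 2)
    if noise_rel > 0:
        y = np.clip(y * (1.0 + noise_rel * rng.standard_normal(len(x))), 0, None)
    atd = ArrivalTimeDistribution(axis=x, intensity=y)
    truth = {"centroid": centroid, "fwhm": fwhm, "tail_tau": tail_tau,
             "second_peak": second_peak, "noise_rel": noise_rel, "seed": seed}
    return atd, truth
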