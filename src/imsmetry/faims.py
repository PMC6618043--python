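"""FAIMS (differential ion mobility) toolkit.

An asymmetric waveform of dispersion voltage DV oscillates ions across a gap
while a DC compensation voltage CV selects which species drift straight and
are transmitted.  Dividing by the gap width converts the voltages into the
dispersion and compensation fields E_D and E_C, which are comparable across
instruments; normalizing by the gas number density gives E_D/N and E_C/N in
Townsend.  The ion-specific quantity behind an E_C(E_D) curve is the
alpha-function

    alpha(E/N) = K(E/N) / K(0) = 1 + a2 (E/N)^2 + a4 (E/N)^4 + ...

The transmitted ion satisfies zero net drift over a waveform period:

    <alpha(|E(t)|/N) * E(t)> = 0,   E(t) = E_D f(t) + E_C,

with f the normalized waveform profile (max|f| = 1, zero mean).  The forward
problem (alpha -> E_C at given E_D) is solved by bracketed root finding; the
inverse problem (curve -> alpha coefficients) is exactly linear in the
even-power coefficients and is solved by least squares.

Sign convention: CV (hence E_C) is taken as superposed on the waveform, so
E_C > 0 for ions whose mobility decreases at higher E/N (a2 < 0) and
E_C < 0 for those whose mobility increases (a2 > 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .constants import TOWNSEND
from .core import GasState
from .errors import (
    ClassificationError,
    DomainError,
    ExtractionError,
    NoSolutionError,
    WaveformError,
)

#: grid size for period-average quadrature (uniform in phase; spectrally
#: accurate for smooth profiles)
_NGRID = 4096


@dataclass(frozen=True)
class FaimsGap:
    """FAIMS gap geometry: width g, length L and span s (all in metres)."""

    width: float
    length: Optional[float] = None
    span: Optional[float] = None
    shape: str = "planar"     # planar | cylindrical | spherical
    inner_diameter: Optional[float] = None  # curved shapes: outer dia of inner electrode
    outer_diameter: Optional[float] = None  # curved shapes: inner dia of outer electrode

    def __post_init__(self):
        if self.width <= 0:
            raise DomainError("gap width must be positive")
        if self.shape not in ("planar", "cylindrical", "spherical"):
            raise DomainError(f"unknown gap shape {self.shape!r}")
        if self.shape != "planar":
            if self.inner_diameter is None or self.outer_diameter is None:
                raise DomainError("curved gaps require electrode diameters")
            if self.outer_diameter <= self.inner_diameter:
                raise DomainError("outer electrode diameter must exceed inner")


class AsymmetricWaveform:
    """Normalized periodic waveform profile f(phase), phase in [0, 1).

    Invariants: max |f| = 1 (so the dispersion voltage is the zero-to-peak
    amplitude) and <f> = 0 over one period.  Construct via the factories
    :meth:`bisinusoidal` or :meth:`rectangular`, or from samples/callable.
    """

    def __init__(self, profile: Callable[[np.ndarray], np.ndarray],
                 frequency: float = 1.0e6, dv: float = 0.0,
                 name: str = "custom", _analytic_moments=None):
        self.frequency = frequency
        self.dv = dv
        self.name = name
        self._analytic_moments = _analytic_moments
        phases = (np.arange(_NGRID) + 0.5) / _NGRID
        samples = np.asarray(profile(phases), dtype=float)
        peak = float(np.max(np.abs(samples)))
        if peak == 0:
            raise WaveformError("zero waveform violates max|f| = 1")
        # refine the peak beyond the coarse grid so the normalization is exact
        # for smooth profiles (the grid midpoint can straddle the extremum)
        i = int(np.argmax(np.abs(samples)))
        lo, hi = phases[max(i - 1, 0)], phases[min(i + 1, _NGRID - 1)]
        res = optimize.minimize_scalar(
            lambda p: -abs(float(np.atleast_1d(profile(np.array([p])))[0])),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-14})
        peak = max(peak, -float(res.fun))
        samples = samples / peak
        mean = float(np.mean(samples))
        # discontinuous profiles sample with O(1/N) mean error; anything beyond
        # that indicates a genuinely asymmetric-in-area (invalid) waveform
        if abs(mean) > 1e-3:
            raise WaveformError(
                f"waveform has non-zero mean over a period (<f> = {mean:.2e})")
        # remove the residual numerical mean so <F_1> is exactly 0
        self._samples = samples - mean

    @property
    def samples(self) -> np.ndarray:
        return self._samples

    def moments(self, n_max: int = 7) -> dict:
        """Profile moments <F_n> = <f^n> for n = 1..n_max (quadrature)."""
        if n_max < 1:
            raise DomainError("n_max must be >= 1")
        return {n: float(np.mean(self._samples**n)) for n in range(1, n_max + 1)}

    def analytic_moments(self, n_max: int = 7) -> Optional[dict]:
        """Closed-form moments when the profile is analytic (else None)."""
        if self._analytic_moments is None:
            return None
        return {n: self._analytic_moments(n) for n in range(1, n_max + 1)}

    @classmethod
    def from_samples(cls, phase, f, frequency: float = 1.0e6, dv: float = 0.0):
        """Waveform from a sampled (phase, f) pair covering one full period."""
        phase = np.asarray(phase, dtype=float)
        f = np.asarray(f, dtype=float)
        if phase.ndim != 1 or phase.shape != f.shape or len(phase) < 4:
            raise WaveformError("need matching 1-D phase/f arrays (>= 4 samples)")
        if np.any(np.diff(phase) <= 0) or phase[0] < 0 or phase[-1] > 1:
            raise WaveformError("phase must be strictly increasing within [0, 1]")
        span = phase[-1] - phase[0]
        if span < 0.99:
            raise WaveformError("samples must cover one full period")

        def profile(p):
            return np.interp(np.mod(p, 1.0), phase, f, period=1.0)

        return cls(profile, frequency=frequency, dv=dv, name="sampled")

    @classmethod
    def bisinusoidal(cls, ratio: float = 2.0, frequency: float = 1.0e6,
                     dv: float = 0.0):
        """Two-harmonic waveform with amplitude ratio ``ratio``:1 between the
        fundamental and its second harmonic (the common 2:1 profile)."""
        a1 = ratio / (ratio + 1.0)
        a2 = 1.0 / (ratio + 1.0)

        def profile(p):
            th = 2.0 * np.pi * p
            return a1 * np.sin(th) + a2 * np.sin(2.0 * th - np.pi / 2.0)

        return cls(profile, frequency=frequency, dv=dv,
                   name=f"bisinusoidal_{ratio:g}to1")

    @classmethod
    def rectangular(cls, high_low_ratio: float = 2.0, frequency: float = 1.0e6,
                    dv: float = 0.0):
        """Ideal rectangular waveform: amplitude +1 for a fraction
        1/(1+r) of the period and -1/r for the rest (r = high/low voltage
        ratio), which makes the mean exactly zero.  Moments are analytic:
        <F_n> = [1 + r (-1/r)^n] / (1 + r)."""
        r = float(high_low_ratio)
        if r <= 1.0:
            raise WaveformError("high/low ratio must exceed 1 for asymmetry")
        x_high = 1.0 / (1.0 + r)

        def profile(p):
            p = np.mod(p, 1.0)
            return np.where(p < x_high, 1.0, -1.0 / r)

        def analytic(n):
            return (1.0 + r * (-1.0 / r) ** n) / (1.0 + r)

        return cls(profile, frequency=frequency, dv=dv,
                   name=f"rectangular_{r:g}", _analytic_moments=analytic)


@dataclass
class AlphaFunction:
    """Even-power mobility field dependence alpha(E/N) = 1 + sum a_2n (E/N)^2n.

    Coefficients are in Td^-2, Td^-4, ...; alpha(0) = 1 by construction.
    ``k0`` (cm^2 V^-1 s^-1), when present, permits absolute K(E/N)
    reconstruction; its relative uncertainty and source are carried along.
    """

    coefficients: tuple       # (a2, a4, ...)
    k0: Optional[float] = None
    u_k0_rel: Optional[float] = None
    k0_source: str = ""

    def __call__(self, e_over_n_td):
        x2 = np.square(np.asarray(e_over_n_td, dtype=float))
        acc = np.ones_like(x2)
        xpow = np.ones_like(x2)
        for c in self.coefficients:
            xpow = xpow * x2
            acc = acc + c * xpow
        return acc if acc.ndim else float(acc)


@dataclass
class FaimsCurve:
    """Measured E_C(E_D) (or normalized, in Td) points with gas context."""

    e_d: np.ndarray
    e_c: np.ndarray
    normalized: bool = False   # True when values are E/N in Td
    gas: str = "N2"
    pressure: Optional[float] = None      # Pa
    temperature: Optional[float] = None   # K

    def __post_init__(self):
        self.e_d = np.asarray(self.e_d, dtype=float)
        self.e_c = np.asarray(self.e_c, dtype=float)
        if self.e_d.shape != self.e_c.shape:
            raise DomainError("e_d and e_c must have the same length")

    def sorted_by_ed(self):
        order = np.argsort(np.abs(self.e_d))
        return self.e_d[order], self.e_c[order]


def fields_from_voltages(dv: float, cv: float, gap: FaimsGap,
                         gas: Optional[GasState] = None):
    """(E_D, E_C) in V/m from dispersion/compensation voltages and the gap
    width; signs are preserved.  With a gas state, also returns (E_D/N,
    E_C/N) in Td, else None."""
    if gap.width <= 0:
        raise DomainError("gap width required to convert voltages to fields")
    e_d = dv / gap.width
    e_c = cv / gap.width
    townsends = None
    if gas is not None:
        n = gas.number_density()
        townsends = (e_d / n / TOWNSEND, e_c / n / TOWNSEND)
    return (e_d, e_c), townsends


def waveform_moments(wf: AsymmetricWaveform, n_max: int = 7) -> dict:
    """Moments <F_n> for n = 2..n_max; <F_1> is asserted ~ 0."""
    m = wf.moments(n_max)
    if abs(m[1]) > 1e-9:
        raise WaveformError(f"<F_1> = {m[1]:.2e} deviates from zero")
    return {n: m[n] for n in range(2, n_max + 1)}


def _net_drift(alpha: AlphaFunction, samples: np.ndarray, ed_td: float,
               ec_td: float) -> float:
    """Period-averaged alpha-weighted field (Td): zero for the transmitted ion."""
    e = ed_td * samples + ec_td
    return float(np.mean(alpha(np.abs(e)) * e))


def forward_ec(alpha: AlphaFunction, wf: AsymmetricWaveform, ed_td: float,
               bracket_frac: float = 0.2, max_expand: int = 3) -> float:
    """Compensation field E_C/N (Td) transmitted at dispersion field E_D/N.

    Solves <alpha(|E|/N) E> = 0 by Brent root finding inside
    [-bracket_frac*E_D, +bracket_frac*E_D], doubling the bracket up to
    ``max_expand`` times if the drift does not change sign inside it.
    """
    samples = wf.samples
    if ed_td == 0:
        return 0.0

    def g(ec):
        return _net_drift(alpha, samples, ed_td, ec)

    half = bracket_frac * abs(ed_td)
    for _ in range(max_expand + 1):
        lo, hi = -half, half
        if g(lo) == 0.0:
            return lo
        if g(hi) == 0.0:
            return hi
        if g(lo) * g(hi) < 0:
            return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-14))
        half *= 2.0
    raise NoSolutionError(
        f"no sign change of the net drift within E_C in [-{half/2:g}, {half/2:g}] Td "
        f"at E_D = {ed_td:g} Td")


def forward_curve(alpha: AlphaFunction, wf: AsymmetricWaveform, ed_td,
                  gas: str = "N2") -> FaimsCurve:
    """E_C(E_D) curve (both in Td) generated from an alpha-function."""
    ed_td = np.asarray(ed_td, dtype=float)
    ec = np.array([forward_ec(alpha, wf, ed) for ed in ed_td])
    return FaimsCurve(e_d=ed_td, e_c=ec, normalized=True, gas=gas)


def extract_alpha(curve: FaimsCurve, wf: AsymmetricWaveform,
                  order: int = 4) -> AlphaFunction:
    """Fit the even-power alpha coefficients to a measured E_C(E_D) curve.

    The transmission condition <alpha(|E|) E> = 0 with E(t) = E_D f + E_C
    fully known per point is linear in the coefficients:

        E_C + sum_n a_2n <E^(2n+1)> = 0,

    so the extraction is a plain least-squares solve.  ``order`` is the
    highest power retained (4 -> a2 and a4).  The curve must be in Td
    (normalized) for the coefficients to be in Td^-2n.
    """
    if order < 2 or order % 2:
        raise ExtractionError("order must be an even integer >= 2")
    n_coeff = order // 2
    if len(curve.e_d) < n_coeff + 1:
        raise ExtractionError(
            f"need at least {n_coeff + 1} curve points for order {order}")
    if not curve.normalized:
        raise ExtractionError(
            "curve must be normalized to Td (E/N) before alpha extraction")
    samples = wf.samples
    rows = []
    rhs = []
    for ed, ec in zip(curve.e_d, curve.e_c):
        e = ed * samples + ec
        rows.append([float(np.mean(e ** (2 * n + 1))) for n in range(1, n_coeff + 1)])
        rhs.append(-float(np.mean(e)))   # = -ec since <f> = 0
    coeffs, residuals, rank, _ = np.linalg.lstsq(np.asarray(rows),
                                                 np.asarray(rhs), rcond=None)
    if rank < n_coeff:
        raise ExtractionError("extraction is underdetermined (rank-deficient design)")
    alpha = AlphaFunction(coefficients=tuple(float(c) for c in coeffs))
    fitted = forward_curve(alpha, wf, curve.e_d, gas=curve.gas)
    alpha.fit_residuals_td = curve.e_c - fitted.e_c
    return alpha


def classify_ion_type(curve: FaimsCurve, rel_tol: float = 0.01):
    """Phenomenological ion type (A/B/C/D/E) from the shape of E_C vs |E_D|.

    Under the unified sign convention (E_C > 0 for mobility falling with
    E/N):

    - A: E_C < 0 with |E_C| uniformly increasing (mobility rising with E/N)
    - B: A-like at low fields, then the derivative reverses
    - C: E_C > 0, uniformly increasing
    - D: C-like, then E_C decreases while remaining positive
    - E: E_C crosses to strongly negative values at high E_D
      (macromolecular dipole alignment)

    These rules are a reconstruction from the narrative definitions; the
    classifier describes only the curve shape and deliberately makes no claim
    about the underlying K(E) form for types B and D.  Monotonicity is judged
    on discrete differences with a tolerance of ``rel_tol * max|E_C|``.
    Returns (type letter, description string).
    """
    ed, ec = curve.sorted_by_ed()
    if not np.all(np.diff(np.abs(curve.e_d)) >= 0):
        warnings.warn("E_D values were not monotone; sorted by |E_D|", stacklevel=2)
    if len(ed) < 3:
        raise ClassificationError("at least 3 points are needed to classify")
    tol = rel_tol * float(np.max(np.abs(ec))) if np.max(np.abs(ec)) > 0 else 0.0
    d = np.diff(ec)
    inc = d > tol
    dec = d < -tol

    def phrase(letter):
        unit = "Td" if curve.normalized else "V/m"
        rng = float(np.max(np.abs(ed)))
        return (f"type {letter} in {curve.gas} up to E_D of {rng:g} {unit}"
                + (" (E_D/N)" if curve.normalized else ""))

    final_ec = ec[-1]
    if np.any(ec > tol) and final_ec < -tol:
        return "E", phrase("E")
    if np.all(ec >= -tol):  # positive branch: mobility falls with E/N
        if np.all(~dec):
            return "C", phrase("C")
        # rises then falls while staying positive
        return "D", phrase("D")
    # negative branch: mobility rises with E/N
    if np.all(~inc):
        return "A", phrase("A")
    return "B", phrase("B")


def operating_mode(polarity: str, k_derivative_sign: int) -> str:
    """FAIMS operating mode label from ion polarity and the sign of dK/dE:
    P1 (cation, K rising), P2 (cation, K falling), N1 (anion, K rising),
    N2 (anion, K falling)."""
    if polarity not in ("+", "-"):
        raise DomainError("polarity must be '+' or '-'")
    if k_derivative_sign == 0:
        raise DomainError("derivative sign must be nonzero")
    base = "P" if polarity == "+" else "N"
    return base + ("1" if k_derivative_sign > 0 else "2")


@dataclass
class ResidenceTime:
    """Upper-bound gap residence time t = g L s / Q_gap."""

    value: float               # s
    upper_limit: bool = True


def residence_time(gap: FaimsGap, q_gap: float) -> ResidenceTime:
    """Residence-time upper bound g*L*s / Q_gap (SI: m, m, m, m^3/s -> s).

    Ions traverse near the gap median where the flow is faster than average,
    so the true residence time is substantially below this estimate.
    """
    if q_gap <= 0:
        raise DomainError("gap flow must be positive")
    if gap.length is None or gap.span is None:
        raise DomainError("gap length and span are required")
    return ResidenceTime(value=gap.width * gap.length * gap.span / q_gap)


def reconstruct_absolute_k(alpha: AlphaFunction) -> Callable:
    """Absolute mobility curve K(E/N) = K(0) * alpha(E/N).

    Requires an alpha-function carrying K(0); the returned callable yields
    (K, u_K_rel) pairs, propagating K(0)'s relative uncertainty
    multiplicatively.  The K(0) provenance is echoed as an attribute.
    """
    if alpha.k0 is None:
        raise DomainError(
            "absolute reconstruction needs the zero-field mobility K(0) "
            "from a linear IMS measurement")

    def k_of(e_over_n_td):
        k = alpha.k0 * alpha(e_over_n_td)
        return k, alpha.u_k0_rel

    k_of.k0_source = alpha.k0_source or "unspecified (verify and report)"
    return k_of
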