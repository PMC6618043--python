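"""The low-field ion-mobility physics layer.

Mobility K is the ratio of the steady-state drift velocity to the applied
field; the reduced mobility K0 rescales K to a reference gas number density;
the collision (momentum-transfer) cross section follows from K0 through the
fundamental low-field equation

    CCS = (3/16) * sqrt(2*pi / (mu * kB * T)) * z*e / (N0 * K0)

with mu the ion-gas reduced mass.  Mobility, not CCS, is the primary
measurand: CCS is derived through this model, and the package keeps that
distinction explicit (method tags and a primary/secondary flag on every CCS).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .constants import (
    A2_PER_M2,
    CODATA_2014,
    DEFAULT_CONVENTION,
    M2_PER_CM2,
    ConstantsSet,
    ReferenceConvention,
    constants_for,
    convert_e_over_n,
)
from .errors import DomainError, InvalidGasStateError

#: molecular masses (Da) of common buffer gases
GAS_MASSES = {
    "He": 4.002602,
    "N2": 28.0134,
    "Ar": 39.948,
    "CO2": 44.0095,
    "H2": 2.01588,
    "O2": 31.9988,
    "air": 28.9647,
    "SF6": 146.055,
}

#: E/N (Td) above which the low-field assumption is questionable
HIGH_FIELD_WARNING_TD = 20.0


@dataclass(frozen=True)
class GasState:
    """Buffer gas: composition (volume fractions), temperature and pressure.

    The number density follows from the ideal-gas law with the active
    constants set.  Mixtures are legal for K0 work (Blanc's law) but CCS
    computation on mixtures is refused unless explicitly requested, because
    CCS requires a single well-defined collision partner mass.
    """

    components: tuple  # of (label, molecular mass Da, volume fraction)
    temperature: float  # K
    pressure: float     # Pa

    def __post_init__(self):
        if self.temperature <= 0 or self.pressure <= 0:
            raise InvalidGasStateError("temperature and pressure must be positive")
        if not self.components:
            raise InvalidGasStateError("gas needs at least one component")
        total = sum(c[2] for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise InvalidGasStateError(
                f"volume fractions must sum to 1 (got {total!r})")
        for label, mass, frac in self.components:
            if mass <= 0 or frac < 0:
                raise InvalidGasStateError(f"bad component {label!r}")

    @classmethod
    def pure(cls, gas: str, temperature: float, pressure: float,
             molecular_mass: Optional[float] = None) -> "GasState":
        mass = molecular_mass if molecular_mass is not None else GAS_MASSES.get(gas)
        if mass is None:
            raise InvalidGasStateError(
                f"unknown gas {gas!r}; supply molecular_mass explicitly")
        return cls(components=((gas, mass, 1.0),),
                   temperature=temperature, pressure=pressure)

    @property
    def is_mixture(self) -> bool:
        return len(self.components) > 1

    @property
    def label(self) -> str:
        if not self.is_mixture:
            return self.components[0][0]
        return "+".join(f"{c[0]}({c[2]:g})" for c in self.components)

    def number_density(self, constants: ConstantsSet = CODATA_2014) -> float:
        """N = p / (kB T), m^-3."""
        return self.pressure / (constants.kB * self.temperature)

    def mean_molecular_mass(self) -> float:
        """Volume-fraction-weighted molecular mass, Da."""
        return sum(m * f for _, m, f in self.components)

    def molecular_mass(self) -> float:
        """Molecular mass (Da) of a pure gas; refuses mixtures."""
        if self.is_mixture:
            raise InvalidGasStateError(
                "gas is a mixture; CCS needs a single collision partner "
                "(use mean_molecular_mass() deliberately if you accept the bias)")
        return self.components[0][1]


@dataclass(frozen=True)
class IonSpecies:
    """An ion: mass (Da), absolute charge and polarity.

    The charge entering the mobility equations is the absolute charge z;
    polarity matters only for FAIMS operating modes.
    """

    mass: float          # Da
    z: int               # absolute charge, >= 1
    polarity: str = "+"  # '+' or '-'
    label: str = ""

    def __post_init__(self):
        if self.mass <= 0:
            raise DomainError("ion mass must be positive")
        if int(self.z) != self.z or self.z < 1:
            raise DomainError("charge must be a positive integer")
        if self.polarity not in ("+", "-"):
            raise DomainError("polarity must be '+' or '-'")

    @property
    def mz(self) -> float:
        return self.mass / self.z


@dataclass
class MobilityResult:
    """A mobility measurement: K and K0 (cm^2 V^-1 s^-1), with provenance."""

    K: float
    K0: float
    convention: ReferenceConvention
    gas: GasState
    E_over_N: Optional[float] = None       # Td
    u_rel: Optional[float] = None          # combined relative standard uncertainty
    constants: ConstantsSet = field(default_factory=lambda: CODATA_2014)

    def to_dict(self) -> dict:
        return {
            "K_cm2_V_s": self.K,
            "K0_cm2_V_s": self.K0,
            "convention": self.convention.label,
            "gas": self.gas.label,
            "temperature_K": self.gas.temperature,
            "pressure_Pa": self.gas.pressure,
            "E_over_N_Td": self.E_over_N,
            "u_rel": self.u_rel,
            "constants": self.constants.to_dict(),
        }


@dataclass
class CcsResult:
    """A collision cross section value (A^2) with its full provenance.

    ``method`` is the platform tag (DT, TW, TIMS, DMA); ``primary`` marks a
    value obtained without calibration.  For calibrated values obtained in
    gas1 against reference values measured in gas2, ``calibration_gas``
    records gas2 so the notation can render gas1->gas2.
    """

    value: float                      # A^2
    gas: str
    method: str = "DT"                # DT | TW | TIMS | DMA
    primary: bool = True
    calibration_gas: Optional[str] = None
    temperature: Optional[float] = None  # K
    u_rel: Optional[float] = None
    flags: dict = field(default_factory=dict)
    constants: ConstantsSet = field(default_factory=lambda: CODATA_2014)

    def __post_init__(self):
        if self.value <= 0:
            raise DomainError("CCS must be positive")
        if self.method not in ("DT", "TW", "TIMS", "DMA"):
            raise DomainError(f"unknown method tag {self.method!r}")

    def to_dict(self) -> dict:
        return {
            "ccs_A2": self.value,
            "gas": self.gas,
            "method": self.method,
            "primary": self.primary,
            "calibration_gas": self.calibration_gas,
            "temperature_K": self.temperature,
            "u_rel": self.u_rel,
            "flags": dict(self.flags),
            "constants": self.constants.to_dict(),
        }


def reduced_mass(m_i: float, m_g: float) -> float:
    """Reduced mass mu = m_i*m_g / (m_i + m_g), in the units of the inputs."""
    if m_i <= 0 or m_g <= 0:
        raise DomainError("masses must be positive")
    return m_i * m_g / (m_i + m_g)


def mobility_from_drift(L: float, t_d: float, delta_v: float, gas: GasState,
                        convention: ReferenceConvention = DEFAULT_CONVENTION,
                        constants: ConstantsSet = CODATA_2014) -> MobilityResult:
    """Mobility from first principles: K = v_d / E = L^2 / (t_d * dV).

    L is the drift length (m), t_d the time spent in the drift region (s) and
    delta_v the voltage drop (V).  K0 applies the p/p0 * T0/T correction under
    the requested reference convention.
    """
    if L <= 0 or t_d <= 0 or delta_v <= 0:
        raise DomainError("drift length, drift time and voltage must be positive")
    cs = constants.with_convention(convention)
    K_si = L * L / (t_d * delta_v)            # m^2 V^-1 s^-1
    K0_si = K_si * (gas.pressure / cs.p0) * (cs.T0 / gas.temperature)
    N = gas.number_density(cs)
    e_over_n = convert_e_over_n(delta_v / L, N)
    if e_over_n > HIGH_FIELD_WARNING_TD:
        warnings.warn(
            f"E/N = {e_over_n:.1f} Td; the low-field assumption behind the "
            "mobility equations may not hold and no high-field correction is applied",
            stacklevel=2)
    return MobilityResult(K=K_si / M2_PER_CM2, K0=K0_si / M2_PER_CM2,
                          convention=convention, gas=gas,
                          E_over_N=e_over_n, constants=cs)


def _mason_schamp_factor(ion: IonSpecies, m_g_da: float, temperature: float,
                         cs: ConstantsSet) -> float:
    """(3/16) sqrt(2 pi / (mu kB T)) * z e, SI units."""
    mu = reduced_mass(ion.mass, m_g_da) * cs.dalton
    if ion.z < 1:
        raise DomainError("zero charge")
    return (3.0 / 16.0) * math.sqrt(2.0 * math.pi / (mu * cs.kB * temperature)) \
        * ion.z * cs.e


def ccs_from_k0(k0: float, gas: GasState, ion: IonSpecies,
                temperature: Optional[float] = None,
                convention: ReferenceConvention = DEFAULT_CONVENTION,
                constants: ConstantsSet = CODATA_2014,
                allow_mixture: bool = False,
                method: str = "DT", primary: bool = True) -> CcsResult:
    """CCS (A^2) from a reduced mobility (cm^2 V^-1 s^-1).

    ``temperature`` defaults to the gas temperature.  Mixtures are refused
    unless ``allow_mixture=True``, in which case the fraction-weighted mean
    gas mass is used (a documented approximation).
    """
    if k0 <= 0:
        raise DomainError("K0 must be positive")
    cs = constants.with_convention(convention)
    T = gas.temperature if temperature is None else temperature
    m_g = gas.mean_molecular_mass() if allow_mixture else gas.molecular_mass()
    ccs_si = _mason_schamp_factor(ion, m_g, T, cs) / (cs.N0 * k0 * M2_PER_CM2)
    return CcsResult(value=ccs_si * A2_PER_M2, gas=gas.label, method=method,
                     primary=primary, temperature=T, constants=cs)


def k0_from_ccs(ccs_a2: float, gas: GasState, ion: IonSpecies,
                temperature: Optional[float] = None,
                convention: ReferenceConvention = DEFAULT_CONVENTION,
                constants: ConstantsSet = CODATA_2014,
                allow_mixture: bool = False) -> float:
    """Inverse of :func:`ccs_from_k0`: reduced mobility (cm^2 V^-1 s^-1) from
    a CCS in A^2."""
    if ccs_a2 <= 0:
        raise DomainError("CCS must be positive")
    cs = constants.with_convention(convention)
    T = gas.temperature if temperature is None else temperature
    m_g = gas.mean_molecular_mass() if allow_mixture else gas.molecular_mass()
    k0_si = _mason_schamp_factor(ion, m_g, T, cs) / (cs.N0 * ccs_a2 / A2_PER_M2)
    return k0_si / M2_PER_CM2


def blanc_mixture_mobility(per_gas_k0: Sequence[tuple]) -> float:
    """Blanc's law: 1/K0_mix = sum_i x_i / K0_i for volume fractions x_i."""
    if not per_gas_k0:
        raise DomainError("empty mixture")
    total = sum(x for x, _ in per_gas_k0)
    if abs(total - 1.0) > 1e-9:
        raise DomainError("volume fractions must sum to 1")
    if any(k0 <= 0 for _, k0 in per_gas_k0):
        raise DomainError("all component mobilities must be positive")
    return 1.0 / sum(x / k0 for x, k0 in per_gas_k0)


def effective_temperature(T_gas: float, m_g: float, v_d: float,
                          constants: ConstantsSet = CODATA_2014) -> float:
    """Two-temperature effective temperature
    T_eff = T_gas + m_g * v_d^2 / (3 kB), with m_g in Da and v_d in m/s."""
    if T_gas <= 0 or m_g <= 0 or v_d < 0:
        raise DomainError("inputs must be positive (v_d may be zero)")
    return T_gas + m_g * constants.dalton * v_d * v_d / (3.0 * constants.kB)


def field_dependence_k0(k0_zero_field: float, alpha, e_over_n: float) -> float:
    """K0 at a reduced field: K0(E/N) = K0(0) * alpha(E/N).

    ``alpha`` is either a callable alpha-function (see
    :class:`imsmetry.faims.AlphaFunction`) or a sequence of even-power
    coefficients (a2, a4, ...) in Td^-2, Td^-4, ...
    """
    if callable(alpha):
        return k0_zero_field * alpha(e_over_n)
    acc = 1.0
    x2 = e_over_n * e_over_n
    xpow = 1.0
    for coeff in alpha:
        xpow *= x2
        acc += coeff * xpow
    return k0_zero_field * acc
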