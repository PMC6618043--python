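"""Physical constants and reference-state conventions.

Every downstream number in the package is computed from a single
:class:`ConstantsSet`, so a result can always state exactly which constant
values produced it.  The default set uses the 2014 CODATA adjustment.  Two
reference states for the reduced mobility K0 are registered: the historical
IM convention (p0 = 1 atm) and the IUPAC STP (p0 = 1 bar).  Failing to state
which one was used changes K0 by the ratio 101325/100000, about 1.3 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .errors import DomainError, InvalidGasStateError

#: 1 Townsend in V m^2 (E/N unit)
TOWNSEND = 1e-21

#: presentation-unit factors (SI <-> customary)
M2_PER_CM2 = 1e-4
A2_PER_M2 = 1e20


class ReferenceConvention(Enum):
    """Reference state (p0, T0) used to define the reduced mobility K0."""

    ATM_273 = ("ATM_273", 101325.0, 273.15)
    STP_IUPAC = ("STP_IUPAC", 100000.0, 273.15)

    def __init__(self, label: str, p0: float, t0: float):
        self.label = label
        self.p0 = p0
        self.T0 = t0


@dataclass(frozen=True)
class ConstantsSet:
    """Traceable registry of the constants used in a computation.

    Parameters are stored in SI base units.  ``N0`` (Loschmidt number at the
    reference state) is always derived as ``p0 / (kB * T0)`` so it can never
    fall out of step with the reference state.
    """

    kB: float = 1.38064852e-23        # Boltzmann constant, J/K (CODATA 2014)
    e: float = 1.6021766208e-19       # elementary charge, C (CODATA 2014)
    dalton: float = 1.660539040e-27   # atomic mass constant, kg (CODATA 2014)
    T0: float = 273.15                # reference temperature, K
    p0: float = 101325.0              # reference pressure, Pa
    codata_tag: str = "CODATA-2014"

    def __post_init__(self):
        if not self.codata_tag:
            raise DomainError("codata_tag must be a non-empty provenance label")
        for name in ("kB", "e", "dalton", "T0", "p0"):
            if getattr(self, name) <= 0:
                raise DomainError(f"constant {name} must be positive")

    @property
    def N0(self) -> float:
        """Number density (m^-3) of an ideal gas at the reference state."""
        return self.p0 / (self.kB * self.T0)

    def with_convention(self, convention: ReferenceConvention) -> "ConstantsSet":
        """Return a copy whose reference state matches ``convention``."""
        return replace(self, p0=convention.p0, T0=convention.T0)

    def to_dict(self) -> dict:
        return {
            "kB": self.kB,
            "e": self.e,
            "dalton": self.dalton,
            "T0": self.T0,
            "p0": self.p0,
            "N0": self.N0,
            "codata_tag": self.codata_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstantsSet":
        keys = {"kB", "e", "dalton", "T0", "p0", "codata_tag"}
        return cls(**{k: v for k, v in d.items() if k in keys})


#: default constants: CODATA 2014, 1-atm reference state
CODATA_2014 = ConstantsSet()

#: default reference convention used by the whole package
DEFAULT_CONVENTION = ReferenceConvention.ATM_273


def constants_for(convention: ReferenceConvention = DEFAULT_CONVENTION,
                  base: ConstantsSet = CODATA_2014) -> ConstantsSet:
    """Constants set with the reference state of ``convention``."""
    return base.with_convention(convention)


def convert_e_over_n(E: float, N: float) -> float:
    """Reduced field E/N in Townsend for field strength E (V/m) and
    number density N (m^-3).  1 Td = 1e-21 V m^2."""
    if N <= 0:
        raise InvalidGasStateError("number density must be positive")
    if E < 0:
        raise DomainError("field strength must be non-negative")
    return (E / N) / TOWNSEND


def convention_shift(K0: float,
                     from_convention: ReferenceConvention,
                     to_convention: ReferenceConvention) -> float:
    """Re-express a reduced mobility under a different (p0, T0) convention.

    K0 is proportional to p/p0 * T0/T, so switching the reference state
    multiplies it by (p0_from/p0_to) * (T0_to/T0_from).  Between the 1-atm
    and 1-bar conventions the relative change is 101325/100000 - 1 = 1.325 %.
    """
    factor = (from_convention.p0 / to_convention.p0) * (to_convention.T0 / from_convention.T0)
    return K0 * factor
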