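"""From a drift-tube measurement to a reduced mobility and a CCS.

A single drift measurement (length, drift time, voltage) gives the mobility
K; normalizing by the gas state gives K0; the low-field mobility equation
turns K0 into a collision cross section.  The printed notation encodes the
method, primary status, gas and temperature, and the uncertainty budget
propagates the standard uncertainties of length, temperature and pressure.
"""

from imsmetry import (
    GasState,
    IonSpecies,
    UncertaintyBudget,
    ccs_from_k0,
    format_notation,
    mobility_from_drift,
)

gas = GasState.pure("N2", temperature=298.0, pressure=530.0)
ion = IonSpecies(mass=1000.0, z=1, label="peptide-like test ion")

mob = mobility_from_drift(L=0.78, t_d=0.025, delta_v=1000.0, gas=gas)
print(f"K   = {mob.K:8.3f} cm^2 V^-1 s^-1   (drift velocity / field)")
print(f"K0  = {mob.K0:8.4f} cm^2 V^-1 s^-1   ({mob.convention.label} reference state)")
print(f"E/N = {mob.E_over_N:8.3f} Td            (low-field regime check)")

ccs = ccs_from_k0(mob.K0, gas, ion)
print(f"CCS = {ccs.value:8.2f} A^2            notation: "
      f"{format_notation(ccs, include_temperature=True)}")

# uncertainty budget: 0.1 % on L (exponent 2), 0.2 % on T, 0.1 % on p
budget = UncertaintyBudget(components=[("L", 0.001, 2.0), ("T", 0.002, 1.0),
                                       ("p", 0.001, 1.0)], n_replicates=6)
print(f"u_c = {100 * budget.u_c:.3f} %, k_p(n=6, 95%) = {budget.k_p:.2f}, "
      f"U_95 = {100 * budget.U_p:.3f} %")
# The expanded uncertainty U_95 is the half-width of the interval expected to
# contain the measurand with 95 % confidence given 6 replicates.
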