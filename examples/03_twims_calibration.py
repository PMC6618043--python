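"""Traveling-wave calibration with a power law and calibrant matching.

Reference ions of known drift-tube CCS are fitted as CCS' = A t'^N; an
unknown ion's CCS follows from its arrival time.  The advisory report warns
when calibrants and analytes are mismatched in charge or reference gas.
"""

from imsmetry import (
    GasState,
    IonSpecies,
    TwimsForm,
    apply_twims,
    calibrant_match_report,
    fit_twims,
    format_notation,
)
from imsmetry.synthetic import make_twims_set

gas = GasState.pure("N2", temperature=298.0, pressure=300.0)
species = [dict(mz=250.0 + 300.0 * i, z=1, ccs=150.0 + 50.0 * i,
                chem_class="peptide") for i in range(6)]
cals, truth = make_twims_set(TwimsForm.POWER, {"A": 18000.0, "N": 0.5},
                             gas, species, seed=7, noise_rel=0.005)

model = fit_twims(cals, TwimsForm.POWER, gas)
print(f"fitted law: CCS' = {model.coefficients['A']:.0f} * t'^"
      f"{model.coefficients['N']:.3f}  (truth A=18000, N=0.5)")

analyte_t, analyte_mz = cals[3].t_arrival * 1.02, 1300.0
res = apply_twims(model, analyte_t, analyte_mz, 1)
print(f"analyte CCS = {res.value:.1f} A^2 "
      f"(+/- {100 * res.flags['prediction_halfwidth_rel']:.1f} % 95% band), "
      f"notation {format_notation(res)}")
print("assumption carried on every TW result:", res.flags["assumptions"][0])

protein = IonSpecies(mass=150000.0, z=15, label="protein 15+")
for finding in calibrant_match_report(cals, [protein], drift_gas="N2"):
    print("advisory:", finding["rule"], "-", finding["detail"])
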