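"""Trapped-IMS first-order calibration: K0 = a + b / Ve.

Calibrant ions of known reduced mobility anchor the elution-voltage scale;
an analyte's K0 and CCS follow from its elution voltage.  The calibration is
fingerprinted to its instrument settings and refuses to apply elsewhere.
"""

from imsmetry import GasState, IonSpecies, apply_tims, fit_tims_first_order
from imsmetry.synthetic import make_tims_calibrants

FP = {"scan_rate_V_per_s": 120.0, "vramp": (100.0, 220.0),
      "p1_mbar": 2.6, "p2_mbar": 1.2}

pairs, truth = make_tims_calibrants(a=0.10, b=150.0,
                                    k0_values=[0.8, 0.95, 1.1, 1.25, 1.4, 1.6],
                                    seed=3, noise_rel=0.003, fingerprint=FP)
model = fit_tims_first_order(pairs, fingerprint=FP)
print(f"fitted a = {model.a:.4f}, b = {model.b:.2f} (truth a=0.10, b=150.0)")

gas = GasState.pure("N2", temperature=305.0, pressure=250.0)
ion = IonSpecies(mass=800.0, z=1)
mob, ccs = apply_tims(model, ve=140.0, ion=ion, gas=gas, query_fingerprint=FP)
print(f"analyte at Ve = 140 V: K0 = {mob.K0:.4f} cm^2 V^-1 s^-1, "
      f"CCS = {ccs.value:.1f} A^2 (u_rel {100 * ccs.u_rel:.2f} %)")
print("validity: coefficients are tied to", sorted(FP))
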