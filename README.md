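# imsmetry

Metrology for ion-mobility mass spectrometry: mobility/CCS conversion under
explicit constant conventions, calibration workflows for every major IM
platform, GUM-style uncertainty budgets, and the community reporting and
notation conventions.

## Who this is for

Practitioners of ion mobility–mass spectrometry (proteomics, metabolomics,
structural biology) who need to turn raw arrival times, elution voltages or
compensation-field curves into reduced mobilities *K*₀ and collision cross
sections (CCS) **with a defensible uncertainty statement**, and reviewers or
database curators who need to check that reported values are traceable.

## The science in brief

An ion drifting through a buffer gas under a weak field *E* reaches a steady
velocity *v*_d; its mobility is *K* = *v*_d/*E*. Normalizing to a reference
gas number density gives the reduced mobility

&nbsp;&nbsp;&nbsp;&nbsp;*K*₀ = *K* · (*p*/*p*₀) · (*T*₀/*T*),

where the reference state is either 1 atm/273.15 K (historical IM convention)
or 1 bar/273.15 K (IUPAC STP) — an unstated choice shifts *K*₀ by 1.3 %, which
is why every result object in this package carries its constants set and
convention. The collision (momentum-transfer) cross section follows from the
fundamental low-field equation

&nbsp;&nbsp;&nbsp;&nbsp;CCS = (3/16) · √(2π/(μ·k_B·T)) · *z·e* / (*N*₀·*K*₀),

with μ the ion–gas reduced mass. Mobility is the primary measurand — CCS is
derived through this model — so every CCS result records its method (DT, TW,
TIMS, DMA), whether it is primary or calibrated, and the reference gas.

Calibration laws implemented:

| platform | law |
|---|---|
| DTIMS multi-field (primary) | *t*_A = slope·(1/ΔV) + *t*₀, *K*₀ from the slope |
| DTIMS single-field | *t*_A = *t*_fix + β·γ·CCS, γ = √(*m*ᵢ/(*m*_g+*m*ᵢ))/*z* |
| TWIMS | CCS′ = *A·t*′^*N* (power), log-linear, quadratic, offset power; CCS′ = CCS·√μ/*z*, *t*′ = *t*_A − *c*·√(*m*/*z*) |
| TIMS | *K*₀ = *a* + *b*/*V*_e (first order) and the scan-rate method *t*_total = *t*₀ + (*V*_e/*V*_ramp)·*t*_ramp |
| DMA | linear voltage ↔ 1/*K*₀ law |
| FAIMS | α(E/N) = 1 + a₂(E/N)² + a₄(E/N)⁴ + …, forward/inverse transmission model for E_C(E_D) curves |

Uncertainty machinery follows the GUM: combined standard uncertainties by
quadrature with the model's sensitivity exponents (the drift length enters as
*L*², the temperature enters CCS with exponent ½), coverage factors from
Student-*t* quantiles at *n*−1 degrees of freedom, type-B triangular
evaluations, and a seeded Monte-Carlo propagator.

## Worked example

```python
from imsmetry import (GasState, IonSpecies, mobility_from_drift,
                      ccs_from_k0, format_notation)

gas = GasState.pure("N2", temperature=298.0, pressure=530.0)
ion = IonSpecies(mass=1000.0, z=1)
mob = mobility_from_drift(L=0.78, t_d=0.025, delta_v=1000.0, gas=gas)
ccs = ccs_from_k0(mob.K0, gas, ion)
print(mob.K, mob.K0, ccs.value, format_notation(ccs, include_temperature=True))
```

prints

```
K   =  243.360 cm^2 V^-1 s^-1   (drift velocity / field)
K0  =   1.1668 cm^2 V^-1 s^-1   (ATM_273 reference state)
E/N =    9.952 Td            (low-field regime check)
CCS =   176.04 A^2            notation: ^DT,1ry^CCS_N2,298
```

(the formatted lines are from `examples/01_mobility_and_ccs.py`): a 1 kDa
singly-charged ion drifting 0.78 m in 25 ms under 1000 V at 530 Pa of
nitrogen has a reduced mobility of 1.167 cm² V⁻¹ s⁻¹ and a nitrogen CCS of
176 Å², measured by the primary drift-tube method at 298 K — which is exactly
what the notation string `^DT,1ry^CCS_N2,298` encodes.

The `examples/` directory holds one short narrative script per capability:

- `01_mobility_and_ccs.py` — drift measurement → K, K₀, CCS, notation, budget
- `02_dtims_multifield.py` — primary multi-field regression with uncertainty
- `03_twims_calibration.py` — traveling-wave power-law fit and calibrant matching
- `04_tims_calibration.py` — trapped-IMS first-order calibration with settings fingerprint
- `05_faims_alpha.py` — waveform moments, E_C(E_D) curves, α-function extraction, ion typing

A thin CLI mirrors the main workflows (`imsmetry convert`, `imsmetry
calibrate dtims-multifield|dtims-singlefield|twims|tims-first-order|tims-scan-rate|dma-linear`,
`imsmetry faims moments|extract-alpha|classify`, `imsmetry validate`,
`imsmetry spectrum centroid`, `imsmetry simulate`); run any with `--help` for
the CSV/JSON schemas.

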