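# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `imsmetry`.

## Constants and conventions

All internal computation is in SI base units; the customary presentation
units (cm² V⁻¹ s⁻¹ for mobility, Å² for CCS, Td for E/N, mbar for TIMS
pressures) are applied only at I/O boundaries. The default `ConstantsSet`
hard-codes the 2014 CODATA values (k_B = 1.38064852×10⁻²³ J/K,
e = 1.6021766208×10⁻¹⁹ C, atomic mass constant 1.660539040×10⁻²⁷ kg); a
caller may supply an overriding set, and whichever set was used is embedded
in every serialized result so numbers remain re-derivable if constants are
revised. The reference number density N₀ is always recomputed as
p₀/(k_B·T₀), never stored, so it cannot drift out of step with the reference
state.

Two reference conventions are registered for K₀: `ATM_273`
(p₀ = 101 325 Pa, T₀ = 273.15 K; the default, because it is the state most
published IM values assume) and `STP_IUPAC` (p₀ = 100 000 Pa). Exactly one is
active per computation and is recorded on every result; converting between
them multiplies K₀ by (p₀,from/p₀,to)·(T₀,to/T₀,from) = 1.01325 between the
two registered states.

## The physics layer

- K = L²/(t_d·ΔV) from first principles; K₀ = K·(p/p₀)·(T₀/T).
- CCS from the low-field momentum-transfer equation,
  CCS = (3/16)·√(2π/(μ k_B T))·z e/(N₀ K₀). The inverse is closed-form, and
  the K → K₀ → CCS → K₀ → K chain closes to better than 10⁻⁹ relative (tested).
- Masses are accepted in Da and converted with the declared Da→kg factor.
- Charge is stored as the absolute integer z; polarity is a separate field
  used only by the FAIMS operating-mode logic.
- Blanc's law (1/K₀,mix = Σ xᵢ/K₀,ᵢ) covers gas mixtures for mobility work,
  but CCS computation on mixtures is refused by default: the reduced mass of
  "the" collision partner is undefined in a mixture. Passing
  `allow_mixture=True` uses the fraction-weighted mean gas mass and is the
  caller's explicit acceptance of that bias.
- The two-temperature effective temperature T_eff = T + m_g v_d²/(3 k_B) is
  available for field-heating estimates. No higher-order kinetic-theory
  correction to the CCS equation is applied anywhere; when the computed E/N
  exceeds 20 Td a warning states that the low-field assumption is in doubt.
  The 20 Td threshold is the conventional upper edge of low-field DMA
  operation and is a warning, not a gate.

## Calibration workflows

All platform calibrations reduce to a straight line in a transformed space
and share one OLS/WLS engine that carries slope/intercept standard errors,
residuals, r², and a Student-t prediction band for one future observation
(so bands widen when calibrants are few — degrees of freedom = points −
parameters). Calibration curves are always fitted with the measured quantity
as the regressor, because prediction bands are defined for y given x.

**Multi-field drift tube (primary).** t_A regressed on 1/ΔV; OLS by default
(equal-variance assumption), WLS when per-point u(t_A) is supplied. The
combined standard uncertainty of K₀ is the quadrature of 2u(L)/L, u(T)/T,
u(p)/p and u(slope)/slope; for CCS the temperature exponent drops to ½
(the √T in the cross-section equation partially cancels the T in K₀) and
u(z)/z, u(μ)/μ are added. Residual curvature — which can indicate
field-dependent mobility or a voltage-dependent effective length — is
flagged by a t-test on a quadratic term fitted to the residuals at α = 0.05;
the test is skipped when residuals are at floating-point noise level
(noiseless synthetic data would otherwise trigger spurious flags).

**Single-field drift tube.** t_A = t_fix + β·γ·CCS with
γ = √(m_i/(m_g+m_i))/z. Only the aggregate β is identifiable from a
single-field fit (its two physical contributions cannot be separated without
multi-field data), so only β is fitted. CCS for an unknown is the inverse
linear map; its uncertainty is the regression prediction half-width mapped
back through β·γ. Applying the calibration at t_A ≤ t_fix is rejected as
unphysical.

**Traveling wave.** Reference values are reduced to CCS′ = CCS·√μ/z
(proportional to 1/K₀; the instrument constant R, which contains the unknown
effective temperature, is never computed — it is absorbed into the fitted
coefficients, and the assumption that R is identical for calibrants and
analytes is recorded on every TW result). Times are corrected to
t′ = t_A − c·√(m/z). Four fit forms: power law and its log-linear statement
(both fitted by least squares in log-log space, hence identical by
construction), a quadratic (linear least squares), and an offset power law
CCS′ = A(t′−t₀)^N fitted by bounded nonlinear least squares with t₀
initialized at 0 and bounded below min(t′) (prevents a negative base).
Calibrations are fingerprinted with the instrument settings; applying a
model under different settings warns (or raises in strict mode). Advisory
checks flag charge-state and chemical-class mismatch and reference-gas
crossover (rendered as gas1→gas2 in the notation); rows with calculated
(theoretical) reference CCS are rejected outright since they are not
traceable to the SI.

**Trapped IMS.** The axial field model E(z,t) is the ramp-shape function
s(z) (linear by default, caller-supplied otherwise) times the scanned
plateau E₀ − βt, continuous at the analyzer center. The scan-rate method
fits t_total against t_ramp at fixed V_ramp (intercept t₀, slope·V_ramp =
V_e) and rejects inputs whose V_ramp varies. The first-order calibration is
OLS of reference K₀ on 1/V_e; the fitted a, b are valid only for the exact
settings (scan rate, range, pressures), enforced by an equality check on a
settings fingerprint, and models can be explicitly invalidated. The
scan-number → V_e mapping must be supplied by the data (it is
instrument-specific); the assumption of an average post-IMS flight time is
recorded on the model rather than corrected.

**DMA.** The generic linear voltage ↔ 1/K₀ law with studentized-residual
outlier flagging (threshold 3, flagged never dropped).

## FAIMS

The waveform is a normalized periodic profile f with max|f| = 1 (so the
dispersion voltage is zero-to-peak by construction) and zero mean. Profiles
are sampled on a 4096-point uniform phase grid — spectrally accurate moments
for smooth (harmonic-sum) profiles; the peak is refined off-grid by bounded
scalar minimization so the normalization is exact. Ideal rectangular
profiles carry closed-form moments ⟨F_n⟩ = [1 + r(−1/r)ⁿ]/(1+r) as an
independent check; their uniform-grid moments agree only to O(1/N) because
of the discontinuities, and the mean-zero tolerance (10⁻³ before residual
mean removal) is set accordingly.

The transmission condition is zero net drift over a period,
⟨α(|E|/N)·E⟩ = 0 with E(t) = E_D·f(t) + E_C and α the even polynomial
1 + a₂(E/N)² + a₄(E/N)⁴ + …  The forward problem (α → E_C) is solved by
Brent root finding in a bracket E_C ∈ ±0.2·E_D, doubled up to three times if
the drift does not change sign — compensation fields are small fractions of
dispersion fields in practice. The inverse problem is *exactly linear* in
the coefficients once (E_D, E_C) are measured, because E(t) is then fully
known: E_C + Σ a₂ₙ⟨E^(2n+1)⟩ = 0 per curve point. Extraction is therefore a
plain least-squares solve, requiring at least order/2 + 1 points; no
iterative deconvolution is needed.

Sign convention: E_C is taken as superposed on the waveform, giving E_C > 0
for ions whose mobility falls at higher E/N (a₂ < 0) and E_C < 0 for the
opposite — verified by the leading-order relation
E_C ≈ −a₂·E_D³·⟨F₃⟩/(N²·(1+3a₂E_D²⟨F₂⟩/N²)), which also shows that the
±a₂ antisymmetry of E_C is exact only in the small-field limit.

Ion types are classified from the discrete shape of E_C vs |E_D| (tolerance
1 % of max|E_C| on differences to absorb noise): A = negative branch,
magnitude uniformly increasing; B = A-like then derivative reversal;
C = positive, uniformly increasing; D = C-like then decreasing while
positive; E = crossing from positive to negative at high E_D. These rules
are a reconstruction from the narrative definitions under the unified sign
convention (the canonical tabulation is published only as a figure), and the
classifier describes *curve shape only* — types B and D do not determine the
shape of K(E), so no K(E) claim is ever emitted. The output phrase embeds
the gas and covered E_D range, since type assignments are gas- and
range-specific. Operating-mode labels (P1/P2/N1/N2) combine ion polarity
with the sign of dK/dE. Residence time g·L·s/Q_gap is returned tagged as an
upper limit (ions ride the faster-than-average median flow). Reporting rule:
fields (V/m) for ~1 atm data, Townsend units for other pressures.

## Spectra and reporting

The ATD container enforces a strictly monotone axis, non-negative
intensities, and an axis-kind label naming what was actually measured
(arrival time, scan number, elution voltage — "drift time" is not a legal
label for an arrival-time axis). Centroids: apex (ties broken toward the
smaller axis value and flagged — a deterministic choice where none is
standard), single-Gaussian nonlinear fit, or intensity-weighted mean; FWHM
by linear interpolation of the half-maximum crossings. No multi-peak
deconvolution beyond windowing is attempted.

ATD → CCSD uses a discrete Jacobian: samples are treated as bins with edges
midway between samples, and intensities are rescaled by the bin-width ratio.
This conserves the bin-integrated intensity exactly for any monotone
transform (linear or not) and makes the transform exactly invertible; the
inverse parameters are stored on the output, which is labeled "apparent
CCSD". Windows containing more than one declared charge state are refused.

The notation formatter renders ^method[,1ry]^CCS_gas[→refgas][,T]; secondary
TW/TIMS/DMA values without calibration-gas provenance are a formatting
error. The report validator checks per-platform required-field lists
reconstructed from the narrative reporting recommendations (the canonical
table is a figure); the rule set is versioned
(`reconstructed-from-narrative-v1`), each finding carries its justification,
findings are monotone (adding a field never adds a finding), and an empty
record never passes. Stating a FAIMS dispersion voltage peak-to-peak is an
explicit failure — zero-to-peak is required.

## Uncertainty machinery

Combined standard uncertainties assume uncorrelated components (stated in
every budget); correlated cases go through the Monte-Carlo propagator, which
requires a seed, at least 10³ draws, uses numpy's default PCG64 generator,
and reports mean, standard uncertainty and a percentile interval, raising on
any non-finite model output with the offending draw. Coverage factors are
computed from two-sided Student-t quantiles at ν = n − 1 (normal quantile
for n = ∞), rounded only at presentation: at 95 %, n = 2 → 12.71, 3 → 4.30,
6 → 2.57, ∞ → 1.96. The type-B triangular evaluation is a/√6 for half-width
a (2 % → ≈0.8 % standard, ≈1.6 % expanded at 95 %). The conservative 0.8 %
single-measurement standard-deviation policy for drift-tube values is
available to callers as an explicit budget component, never applied
silently.

## Synthetic data

The generators simulate each platform's measurement chain from known truth:
noise is relative Gaussian applied to the *measured* quantities only (times,
voltages), never to truth parameters, mirroring where noise enters a real
measurement. The default noise is 0.5 % relative — the typical
inter-instrument dispersion of drift-tube cross sections — and TIMS examples
use 0.3 % on elution voltages, the regime in which first-order TIMS
calibration reproduces drift-tube mobilities within about 1 %. Seeds are
mandatory and identical seeds give identical fixtures. The ATD generator
produces Gaussian peaks, optionally exponentially tailed or with a second
conformer, with the protein-like width regime (FWHM ≈ 10 % of the centroid)
as the reference case. What the generators do *not* emulate: diffusion- or
space-charge-driven peak widths (widths are parameters), drift-gas
contamination, velocity-relaxation dynamics in TWIMS, non-Blanc behavior in
mixtures, and dipole alignment in FAIMS (type-E curves can be classified but
not generated from physics). Passing tests therefore demonstrate the
correctness of the estimators and uncertainty machinery under the stated
noise model, not robustness to every instrumental artifact.

## Problem sizes and tolerances

Test and acceptance problem sizes are small by design — 6–16 calibrants per
fit, 200 noise realizations per coverage study, 4096-point waveform grids,
10⁵-draw Monte-Carlo checks — because every quantity here is analytic or a
small regression; these sizes give sampling errors well below the tested
tolerances. Closure tolerances: 10⁻¹² relative for linear-in-parameters
laws on noiseless data, 10⁻⁹ for the mobility/CCS round trip, 10⁻³ on
extracted α coefficients (limited by the forward solver's root tolerance and
grid), 10⁻⁹ on CCSD intensity conservation.

## Known limitations

- No vendor raw-file parsing; inputs are CSV/JSON.
- No trajectory-model or other first-principles CCS computation.
- No transferable (Taylor-expansion) TIMS calibration; only the scan-rate
  and first-order empirical schemes.
- No FAIMS ion-trajectory or dipole-alignment modelling; no gas-flow CFD for
  residence-time distributions (only the printed upper-bound formula).
- No effective-drift-length modelling for drift tubes; the curvature flag is
  diagnostic only.
- Single-Gaussian peak fitting only; overlapping conformers must be windowed.
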