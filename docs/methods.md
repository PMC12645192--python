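# Methods

This note documents the models, conventions, numerical choices and known
limitations of `photokin`. The system under study is donepezil (DPZ,
pKa 8.95) co-dissolved with riboflavin (RF), irradiated with a UV source
(dominant 270 nm line, photon flux 2.31 × 10¹⁷ q s⁻¹) or a visible source
(lines 340–700 nm, 5.51 × 10¹⁸ q s⁻¹) under air or nitrogen bubbling at
pH 2–12.

## Synthetic data model

No raw time-course measurements are deposited for this system, so all
pipeline inputs are generated. The generator's defaults *are* the study
conditions: DPZ 1.00 × 10⁻⁴ M, RF 0.05–0.50 × 10⁻⁴ M, k_obs of order
10⁻³–10⁻¹ min⁻¹, a tenfold aerobic/anaerobic rate ratio, 1 cm path
length, and a 200–700 nm grid at 1 nm.

- **Band shape.** Chromophore absorptivities are sums of Gaussians *in
  wavelength* (not wavenumber) — adequate for synthetic fixtures and kept
  as a documented constant of the model. Band centers sit at the known
  absorption maxima; the 325 nm (DPZ) and 445 nm (RF) peak absorptivities
  equal the assay calibration slopes (1.14 × 10⁴ and 1.15 × 10⁴ M⁻¹ cm⁻¹),
  so the forward model and the assay matrix agree. The remaining band
  amplitudes are typical aryl-ketone / isoalloxazine magnitudes chosen
  once; nothing downstream depends on them except the qualitative UV
  spectrum.
- **Noise.** Additive Gaussian on absorbance/detector signal. A seed is a
  required argument everywhere (no global RNG state); identical seeds give
  bit-identical datasets. Truncation of noisy absorbance at zero happens
  only under an explicit `physical=True` flag, because truncation biases
  the noise distribution.
- **Lamp spectra.** Emission lines are rendered as 2 nm-sigma Gaussians on
  the common grid so lamp/solution overlap integrals are well defined.
  The relative weights of the minor UV lines (0.05 of the 270 nm line)
  are nominal; only the dominant-line position and the total photon
  fluxes carry quantitative weight downstream.
- **Job series.** The 1:1 complex concentration solves the exact quadratic
  mass-action relation at constant total concentration; ΔA is proportional
  to the complex concentration.
- **Chromatograms.** Sum of Gaussian peaks with area = response factor ×
  concentration; the default time grid is one tenth of the narrowest peak
  sigma, which keeps trapezoid areas within 0.1% of nominal.

Because the generator is first-order by construction, passing
recovery tests demonstrates correctness of the *estimators*, not of the
first-order hypothesis for real data; it also omits inner-filter effects,
instrument drift, fluorescence and baseline artifacts.

## Assay

The two-component solve inverts `A = K·C` at 325/445 nm. The
cross-absorptivity matrix is a required input because the off-diagonal
terms are not published: the default uses the calibration slopes on the
diagonal, ε_DPZ(445) = 0 (DPZ does not absorb in the visible) and a
configurable ε_RF(325) (default 3 × 10³ M⁻¹ cm⁻¹; RF does absorb there).
Systems with |det K| below 10⁻¹² times the product of row norms are
rejected as singular.

Calibration statistics follow the standard OLS formulas with n−2 residual
degrees of freedom. **SD of intercept is defined as SE of intercept ×
√n.** The validation tables report both an SE and an SD of the intercept
whose printed ratio is ≈ √10 for n = 10; this definition reconciles them,
and the detection limits derive from the SD. The residual SD is also
exposed (`residual_sd`) and is the right σ estimate when the noise level
itself is of interest.

Plate counts use the half-height convention N = 5.54 (t_R/w½)²; tailing
uses the USP 5%-height convention T = W₀.₀₅/(2f). The reference tailing
factors (0.45/0.65, i.e. fronting peaks) were evidently computed under
some other convention that is not stated; the USP formula is adopted and
the discrepancy simply noted. Job analysis refines the grid maximum with
a parabola through the three surrounding points and labels the complex
1:1 when x*/(1−x*) ∈ [0.8, 1.25].

## Validation statistics

LOD = 3.3 σ/S and LOQ = 10 σ/S, σ = SD of intercept by default (residual
SD by option). The method-comparison test is the pooled-variance
two-sample t-test: with equal group sizes it coincides with Welch's
statistic, and the pooled df (n₁+n₂−2 = 18) is what reproduces the
reported p-value (t = 0.062, p = 0.952 on the paired recovery table).
Reported recoveries are rounded to one decimal for display; raw values
are retained in JSON output.

## Kinetics

- k_obs comes from OLS of **natural-log** concentration on time; a log₁₀
  fit differs only by the 2.303 factor and yields the identical k.
- k₂ is the raw OLS slope of k_obs versus sensitizer concentration in
  M⁻¹ min⁻¹. The reference tables print k₂ values that are consistently
  the OLS slope divided by ≈ 2.5 (e.g. the pH 2.0 visible/aerobic row
  gives an OLS slope of 362 M⁻¹ min⁻¹ against a printed 1.45 in table
  units); the concentration scale used for the printed regression is not
  stated, so the package reports the true slope and leaves the factor
  documented rather than reproduced.
- Quantum yields use the initial-rate convention Φ = k_obs·C₀·V /
  (absorbed einstein min⁻¹), with the absorbed fraction
  f = ∫E(λ)(1−10^(−A(λ)))dλ / ∫E(λ)dλ (trapezoid weights) and Avogadro's
  number 6.02214 × 10²³. Φ > 1 is permitted — the aerobic values reach
  3.46, consistent with chain photochemistry. Within each lamp/condition
  block Φ is proportional to k_obs (the visible/aerobic ratio
  Φ/(k_obs × 10²) is 0.30 constant to <3% across pH); the one anaerobic-UV
  value at pH 4.0 (0.146 against a block-constant ≈ 0.06) breaks the
  proportionality and is treated as a likely misprint, excluded from the
  ratio property.
- Speciation is a monoprotic Henderson–Hasselbalch model (cationic below
  pKa, neutral above; no anionic form exists for DPZ).
- k–pH profile features (bell maximum on pH 2–4, overall minimum,
  monotone flag on pH 5–12) are grid-restricted with no interpolation,
  since the reference profile is reported on integer pH points.
- One matched aerobic/anaerobic cell of the reference dataset (visible,
  pH 12.0, RF 0.10 × 10⁻⁴ M) has a rate ratio of 10.57 — outside the
  nominal "tenfold within 5%" band that all 109 other cells satisfy, and
  not attributable to printed-precision rounding. The package reports the
  data as printed; the corresponding fixture check states the 5% band and
  therefore flags this cell.

## Mechanism simulator

The reaction network transcribes the photosensitization scheme: type I
(triplet RF + DPZ electron transfer, radical deprotonation, oxygen capture
of the DPZ radical), type II (triplet quenching by ³O₂ to ¹O₂, ¹O₂ attack
on DPZ, ¹O₂ relaxation), and the anaerobic route (ground-state RF···DPZ⁺
complex formation, complex excitation/isc, H-abstraction to the
semiquinone RFH˙ plus products, disproportionation 2RFH˙ → RF_ox + RFH₂,
reoxidation of RFH₂ by trace O₂ and radical recombination back to RF).

Design choices:

- **Excitation** is a pseudo-first-order channel (ground state → excited
  singlet at k_exc = lamp flux × absorbed fraction / (V·N_A·C)), not
  radiation transport.
- **Rate constants.** None are published for the elementary steps. The
  defaults in `data/default_rates.yaml` are order-of-magnitude
  literature-scale placeholders: diffusion-limited radical/quenching
  steps ~10⁹–10¹⁰ M⁻¹ s⁻¹, ¹O₂ lifetime ~3.5 µs in water, intrinsic
  triplet decay 1/lifetime for the ~17.5 µs oxygen-free triplet (the
  sub-microsecond aerobic lifetime emerges from the O₂-quenching step at
  saturation), and an H-abstraction branch chosen once so the default
  schemes demonstrate the observed ~10× aerobic/anaerobic ratio. Every
  quantitative test of the simulator is therefore a property —
  conservation, flat dark control, log-linearity, monotone/linear k_obs
  vs [RF], ratio within [5, 20] — never an absolute rate.
- **Oxygen handling.** Aerobic presets buffer ³O₂ at 2.5 × 10⁻⁴ M
  (continuous air bubbling); anaerobic runs start at 1% of saturation,
  enough to drive the reduced-flavin reoxidation steps without letting the
  oxygen pathways dominate.
- **Observable.** The intact substrate is free DPZ plus complexed DPZ
  (complexation sequesters without degrading, and any assay performed on a
  withdrawn sample would count both); `effective_k_obs` fits this pool
  over the window where it stays above 10% of its initial value and flags
  runs with under 5% decay as low-signal instead of fitting noise.
- **Integration.** `scipy.integrate.solve_ivp` BDF with an analytic
  Jacobian assembled from the mass-action stoichiometry; default rtol
  10⁻⁸ with an absolute tolerance scaled ~10 orders below the largest
  initial concentration, which keeps moiety totals (flavin; DPZ-derived)
  constant to better than 10⁻⁸ relative along every trajectory. Buffered
  species are implemented by zeroing their net rate.
- **Anaerobic saturation.** With stoichiometric (non-catalytic) flavin
  turnover, the anaerobic run stalls once the flavin pool is spent
  (roughly one substrate molecule per flavin plus the trace-oxygen
  recycling allowance); the fitted window therefore reflects the
  pre-stall regime. Real systems replenish via back-reactions not in the
  published scheme.

## Assessment

Eco-scale penalty points are shipped as *data* (a ledger CSV), not rules
— they are stated, not derived. The score is 100 − Σpp with the standard
bands (>75 excellent, 50–75 acceptable, <50 inadequate). NEMI quadrants:
PBT-free, hazard-free, 2.0 ≤ pH ≤ 12.0, waste strictly < 50 g. TOC loss is
100(TOC₀−TOC₁)/TOC₀ and the TC = TOC + IC audit passes at |residual| ≤
0.5 ppb. The DPZ–RF mixture row's reported loss (40.00%) is not
reproducible from its own TOC entries ((696−421)/696 = 39.51%), so that
row is reported as data but excluded from recomputed summaries.
Pictogram-based composite scores (GAPI, AGREE, BAGI, RAPI) are out of
scope: their per-attribute assignments exist only as figures and cannot be
recomputed from stated inputs.

## Problem sizes

The test suite and the acceptance script use: 1000-seed noise replicates
for fitter-bias checks, 500-seed calibration replicates for the LOD
recovery property, 20 000 Monte-Carlo draws for error propagation,
61-point trajectories over 120 min for the mechanism runs, and the full
220-cell reference kinetic grid. The whole suite runs in a few seconds on
one CPU.
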