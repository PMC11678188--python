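# Methods

`memtherm` infers the thermodynamics of gel–fluid phase coexistence in
lipid bilayers (pure DPPC and pulmonary-surfactant-like mixtures) from two
kinds of measurements: DSC melting endotherms and temperature series of
nitroxide spin-label ESR spectra.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not emulate.

## DSC reduction

A baseline-subtracted excess heat capacity curve Cp(T) of a two-state
melting transition is summarized by:

- **Tm** — position of the Cp maximum.  Instrument grids are coarse
  relative to the ~0.02 °C precision expected of Tm, so the discrete
  maximum is refined by a parabola through its three surrounding points.
- **ΔHcal** — composite-trapezoid integral of Cp over the transition
  window on the native grid (matching what commercial DSC software does).
- **ΔTm,1/2** — full width at half of the refined peak height, each flank
  located by linear interpolation between bracketing samples.  A flank
  that never reaches half height is reported missing, not guessed.
- **ΔS(Tm) = ΔHcal/Tm**, **ΔHvH = 4·R·Tm²·Cp,max/ΔHcal**, and the
  cooperative unit size **CUS = ΔHvH/ΔHcal**.

Baseline handling: an optional buffer scan is interpolated onto the sample
grid and subtracted, then a polynomial (default degree 1) fitted on two
user-chosen windows flanking the peak is removed.  ΔHcal is exactly
invariant under any baseline the window fit removes.  Temperatures are
Celsius at every user-facing interface and kelvin internally; enthalpies
kcal/mol, entropies cal·mol⁻¹·K⁻¹; R = 1.987204 cal·mol⁻¹·K⁻¹.

### Melting-point depression

The shift of Tm with drug:lipid mole ratio x is fitted with the two-state
ligand-partitioning model

    1/Tm(x) − 1/Tm0 = (R/ΔH) · ln[(1 + KF·x)/(1 + KG·x)],

where KF and KG are the ligand's affinities for the fluid and gel phases
(per mole ratio) and ΔH is the transition enthalpy of the unit carrying
one set of binding sites.  The sign convention makes preferential fluid
binding (KF > KG) depress Tm.  When every lipid offers a binding site the
sites scale with the cooperative unit and ΔH is the per-molecule
calorimetric enthalpy ΔHcal; with that choice the DPPC/nicotine Tm series
gives KF/KG = 1.75 ± 0.30.  Passing the van't Hoff enthalpy instead
(single site per cooperative unit) makes the model degenerate on
sub-kelvin Tm shifts — the reported uncertainty makes that explicit.  The
fit is ordinary least squares in log-parametrized (KG, KF) with the
ratio's uncertainty from the delta method; a flat Tm series returns ratio
1 flagged unbounded.  The adopted functional form is recorded in
`model_id` so alternatives can be added.

## ESR stage

### Lineshape observables

`lineshape_metrics` measures, model-free: the outer hyperfine splitting
2Amax (field of the global high-field minimum minus the global low-field
maximum — absent when either extremum is unresolved at the grid edge), the
central-line peak-to-peak width ΔH0, and the central zero crossing.  Both
metrics are translation-invariant along the field axis.

### Populations by basis decomposition

Inside the coexistence window a spectrum is modeled as a non-negative
superposition of an ordered-phase and a disordered-phase basis spectrum.
Each basis is scaled to unit absorption area (double integral of the
first-derivative trace), so the least-squares weights count spins and the
populations are P_i = w_i/(w_ordered + w_disordered).  This replaces
full slow-motional lineshape simulation: the downstream thermodynamics
needs only the fractions, and on linear mixtures of known bases the
decomposition is exact.  Consequences for real data: basis decomposition
assumes the pure-phase lineshapes are temperature-independent across the
window (or supplied per temperature); gradual lineshape drift biases the
fractions smoothly, a regime the synthetic generator can emulate via its
`model_T_drift` option but the default tests do not probe.

Options and conventions:

- bases come either from the coldest/hottest spectra of the series
  (`endpoints`, valid when the series extends beyond the coexistence
  window on both sides) or are supplied explicitly;
- an optional rigid field alignment (±2 G, chosen by residual, ties to
  the smallest shift) absorbs small field offsets between runs;
- bases with cosine similarity > 0.999 are rejected as unidentifiable;
- per spectrum, a one- vs two-component F-test (α = 0.01) decides whether
  the second component is statistically justified; where it is not, the
  population is set to 0 or 1 toward the better single basis.

### Order parameter

S = ⟨(3cos²θ−1)/2⟩ over the Boltzmann distribution of an orienting
pseudopotential −U/kT = c20·D²₀₀ + c22·(D²₀₂+D²₀,₋₂) + rank-4 terms
(c40, c42, c44, default 0 — the coefficients are dimensionless, in units
of kT).  Quadrature: Gauss–Legendre in cosθ (default 256 nodes; the
integrand is smooth and even, and doubling the nodes moves S by < 1e-8
for |c20| ≤ 10) crossed with a uniform φ rule (128 nodes, exact for the
trigonometric φ dependence); the φ integral is skipped for uniaxial
potentials.  The Boltzmann exponent is max-shifted before exponentiation
so large |c20| cannot overflow.  Note the asymmetric approach to the
perfect-alignment limits: 1 − S ≈ 1/c20 while S + 1/2 ≈ 1/(2|c20|), so at
c20 = ±50 the order parameter is 0.9799 and −0.4900.

## Van't Hoff inference

With K = Kp·P_disordered/P_ordered (Kp the probe's partition coefficient,
default 1; deviations from 1 only shift ΔG and ΔS by R·T·ln Kp and
−R·ln Kp), temperatures where either fraction is below 0.02 are excluded
before taking logs (the logit diverges at the window edges), and ln K is
fitted by ordinary least squares with polynomials in u = 1/T up to cubic:

    ln K = a + b·u + c·u² + d·u³.

u spans only ~1e-4 K⁻¹, so the fit runs in a mean-centered u basis for
conditioning and maps coefficients (and covariance) back to the raw
basis.  Degree can be selected automatically: the highest candidate whose
incremental F-test against the next-lower degree has p < 0.01, ties
toward the lower degree.

Thermodynamics follow analytically:

    ΔG = −R·T·ln K
    ΔH = −R·(b + 2c·u + 3d·u²)
    ΔS = (ΔH − ΔG)/T          (equals −∂ΔG/∂T)
    ΔC = R·(2c·u² + 6d·u³)    (the analytic ∂ΔH/∂T)

Special temperatures — every root of ΔG (phase equilibrium) and of ΔS
(stationary points of ΔG) inside the fitted range — are located by a
0.01 K sign-change scan refined by Brent bisection; multiple ΔG roots are
all reported (ternary mixtures can show two).  Entropy–enthalpy
compensation is quantified by regressing ΔH on ΔS (slope = compensation
temperature) and ΔH on T·ΔS (slope ≈ 1 ⇔ |ΔG| small against the
enthalpic scale).  Uncertainty comes from a residual-resampling bootstrap
of the polynomial fit (percentile 2.5/97.5 bands for every curve and
coefficient; deterministic per seed).

## Synthetic data: what it emulates

The generators provide ground-truth-known stand-ins for the instrument
data:

- **Thermograms**: the unique two-state lineshape consistent with the
  ΔHvH/Cp,max relation, Cp = ΔHcal·(ΔHvH/RT²)·K/(1+K)² with
  K = exp[−(ΔHvH/R)(1/T − 1/Tm)]; a Gaussian pretransition peak of
  prescribed area (no lineshape is established for pretransitions); an
  ascending-power polynomial baseline in (T − Tm); i.i.d. Gaussian noise
  with a mandatory seed.  Default: Tm = 314.15 K, ΔHcal = 8.74 kcal/mol,
  ΔHvH = 2930 kcal/mol, pretransition at 307.15 K — the DPPC values — on
  a 5 mK grid over 300–322 K.
- **Spectra**: three first-derivative pseudo-Voigt lines at center ± A
  and center, with per-line peak-to-peak widths (the Gaussian and
  Lorentzian sub-shapes share their extrema positions, so the nominal
  width is the realized peak-to-peak width).  The default component pair
  — broad/strongly split (A = 28 G, widths 5–7 G) vs narrow (A = 15.2 G,
  widths 1.6–2.2 G) — mimics the contrast between slow-motional gel-phase
  and mobile fluid-phase nitroxide spectra at X band near g = 2
  (center 3350 G).  Not emulated: slow-motional lineshape theory, g/A
  tensor anisotropy, MOMD powder averaging, field modulation artifacts.
  Passing tests therefore certify the decomposition arithmetic and noise
  robustness, not the spectroscopy of real slow-exchange systems.
- **Series**: mixing fractions follow the cubic ln K law exactly
  (P_dis = K/(Kp + K)), components are area-normalized before mixing so
  fractions are recoverable by construction, noise is Gaussian with sd a
  fraction of the clean maximum amplitude (0.02 ≈ signal-to-noise 50).
  Default study conditions: 27 temperatures, 0.5 K steps across
  300–313 K, and a cubic whose ln K runs from −2.55 to +0.85 with steep
  flanks and a mid-window plateau — the pronounced sigmoid of a strongly
  cubic van't Hoff plot, with its ΔG root near the hot edge of the
  window.  The coefficients are generated from that centered description
  (`default_vh_coeffs`) rather than stored as raw numbers, because the
  raw 1/T-basis coefficients are numerically huge and rounding them
  perturbs the curve.

## Problem sizes used by the test suite and acceptance script

Population recovery uses 200 noisy mixtures at signal-to-noise 50;
degree selection uses 100 replicates with fraction noise sd 0.02;
bootstrap bands use 1000 resamples; DSC property checks sweep 100 random
transition specs.  These sizes give stable Monte Carlo rates (recovery
97%, cubic detection 100%) at a few seconds of runtime each.

## Known limitations

- The basis-decomposition populations are exact only when the pure-phase
  lineshapes are known; with endpoint bases the series must reach purity
  at both ends, which the default synthetic window (fractions 0.07–0.67)
  deliberately does not — pipeline runs on it must supply the bases.
- The melting-point-depression model treats binding as ideal and
  site-per-lipid; curvature in 1/Tm(x) is weakly informative about KG and
  KF separately, so their ratio is the robust quantity.
- Polynomial van't Hoff curves should not be extrapolated outside the
  fitted temperature range; the curve evaluator enforces this.
- ΔC inherits two derivatives of the ln K fit and is therefore the most
  uncertainty-amplified output; consult the bootstrap bands.
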