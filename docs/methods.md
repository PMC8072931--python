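# Methods

Models, parameter conventions, numerical choices and limitations of the
`metallobind` package. Everything stated here is either exact algebra or
is enforced by the test suite / acceptance script; no empirical claim is
made beyond what those compute.

## 1. Spectrophotometric binding analysis (`metallobind.titration`)

### Model

A 1:1 equilibrium P + PtL ⇌ P·PtL with association constant
K = [P·PtL]/([P][PtL]). The differential absorbance at the analysis
wavelength λ* is ΔA = Δε·x·l, where x is the bound-adduct molarity and
Δε = ε_bound − ε_free (negative for hypochromism). For *n* independent
equivalent sites the site concentration is n·C_P and mass action gives
the quadratic

K·x² − (K(C_PtL + nC_P) + 1)·x + K·n·C_P·C_PtL = 0,

solved in the cancellation-free form x = 2c/(b + √(b² − 4ac)) (the naive
quadratic formula loses all significant digits when Kc ≪ b²).

### Estimators

* **Iterative double-reciprocal (1:1).** Mass action rearranges exactly
  to C_PtL·C_P/ΔA + ΔA/Δε² = (C_PtL + C_P)/Δε + 1/(KΔε). Iteration 0
  drops the ΔA/Δε² term, reads Δε from the reciprocal slope, later
  passes re-add the term until Δε is self-consistent (relative
  tolerance 10⁻⁶); then K = slope/intercept.
* **Scatchard (equivalent sites).** C_P(C_PtLΔε − ΔA)/ΔA regressed on
  (C_PtLΔε − ΔA): slope = 1/(nΔε), intercept = 1/(nK). Δε is an input
  (spectral calibration of the bound species, or the 1:1 fit when that
  model applies — feeding a mis-specified 1:1 amplitude to an n ≠ 1
  system biases both n and K).
* **Nonlinear oracle.** Direct Levenberg–Marquardt fit of
  ΔA = Δε·x(K) over (log₁₀K, Δε), started from a coarse log-spaced K
  grid. It shares nothing with the linearizations except the
  mass-action solver and is used to cross-check them (agreement ≤ 0.1%
  on noiseless data for K = 10²–10⁵ M⁻¹).

### Numerical choices

* **Steffensen acceleration.** The plain fixed-point update Δε ← 1/slope
  converges only linearly, and in the near-stoichiometric large-K
  regime its contraction factor exceeds 1 (the true root becomes
  repelling and a spurious second self-consistent root appears).
  Aitken Δ² extrapolation after every two plain updates (Steffensen's
  method) converges at second order and also lands on locally repelling
  fixed points. The iteration is run from two starts — the iteration-0
  estimate and the saturation-amplitude estimate ΔA_max/min(C_PtL,
  nC_P) — and the root whose final regression has the smaller residual
  sum of squares wins (zero at the true root on model data).
* **Jackknife standard errors (default).** The reciprocal transform
  amplifies noise heteroskedastically, so the regression delta-method
  SE of K is badly optimistic (±2 SE coverage well under 50% at
  realistic noise). The default SE is a deterministic leave-one-out
  jackknife over isotherm points, which re-runs the full iterative
  procedure per replicate (measured coverage ≈ 85%). `se_method="delta"`
  keeps the fast analytic error.
* **Diagnostics.** Points with ΔA = 0 or the wrong sign are dropped with
  a warning (≥ 4 usable protein-bearing points required); an intercept
  t-ratio < 2 flags K unreliable (unsaturated isotherm); a
  Wald–Wolfowitz runs test on the final residuals flags systematic
  curvature ("distorted isotherm").

### Parameters and conventions

| quantity | unit | default | why |
|---|---|---|---|
| `tol` (Δε convergence) | relative | 1e-6 | far below data noise, cheap |
| `max_iter` | — | 100 | Steffensen converges in ≤ ~10 |
| K | 1/M | — | association constant |
| Δε | 1/(M·cm) | — | signed; ΔA normalized to l = 1 cm |
| ε₂₈₀ (A280 assay) | 1/(M·cm) | 38,940 (lysozyme), 8,640 (ribonuclease A) | standard protein quantitation |

Concentrations attached to each titration point are the **actual in-cell
analytical totals** after dilution by the cumulative titrant volume; the
linearizations hold exactly per point even as C_PtL varies, so no
dilution rescaling of the spectra is needed (a `correct_dilution`
rescaling onto the constant-C_PtL convention is provided for data
recorded that way — the isosbestic point is addition-invariant only on
that scale).

## 2. DSC unfolding thermodynamics (`metallobind.dsc`)

### Model

Reversible two-state unfolding N ⇌ D:

* ΔG(T) = ΔH_vH(1 − T/T_d) + ΔCp[(T − T_d) − T·ln(T/T_d)]
* K_eq = exp(−ΔG/RT), f_D = K_eq/(1 + K_eq)
* Cp_exc = ΔH(T)·df_D/dT + f_D·ΔCp, with the analytic derivative
  df_D/dT = ΔH(T)·K_eq/(RT²(1+K_eq)²) and ΔH(T) = ΔH_vH + ΔCp(T − T_d).

R = 8.314462618×10⁻³ kJ/(mol·K); all internal temperatures are Kelvin,
file I/O converts from the instrument's Celsius convention.

Model-free observables: ΔH_cal (trapezoidal area), T_d (peak maximum,
quadratic-refined below the grid step), ΔS(T_d) = ΔH/T_d. The two-state
fit adds ΔH_vH and the cooperativity ratio ΔH_vH/ΔH_cal; a fit with RMS
residual > 5% of the peak height (or a non-converged optimizer) is
status `FAILED` — an equimolar mixture of populations unfolding 6 K
apart leaves ≈ 7% and is correctly rejected, whereas two-state peaks at
ΔH ≈ 450 kJ/mol are ≈ 8 K wide, so more closely spaced mixtures
genuinely merge into an effective two-state endotherm.

Two analytic facts the tests pin down: the peak height is
ΔH²/(4RT_d²), and with ΔCp = 0 the Cp_exc maximum is **not** exactly at
T_d — expanding dCp_exc/dT = 0 to first order puts it at
T_d − 4R²T_d³/ΔH² (≈ 0.06 K below T_d for ΔH = 450 kJ/mol, T_d = 350 K).

### Baseline and corrections

* **Sigmoidal progress baseline.** Straight lines fitted in pre- and
  post-transition windows (defaults: first/last 10% of the scan) are
  connected by the normalized running integral of the corrected signal
  (the unfolding progress), iterated twice so the progress curve is
  computed on an already-flattened signal. Windows overlapping the peak
  are rejected; "peak present" is judged against the fixed 10% scan
  edges so a window placed over the peak cannot mask itself. Note the
  exponential tails of a two-state transition extend ~±15 K: with T_d
  within ~20 K of the scan end the post-window still contains real
  signal and the correction degrades.
* **Native-loss correction.** Sequential native-protein losses (e.g.
  12% then 9% over incubation) compose multiplicatively; Cp_exc is
  divided by ∏(1 − loss_i).
* exp(−ΔG/RT) is evaluated with its argument clipped to ±700 to avoid
  overflow far below T_d at large ΔH.

## 3. ESI-MS adduct bookkeeping (`metallobind.adducts`, `.formula`)

A bound fragment of formal charge q displaces q protons, so k bound
fragments shift the neutral mass by M = M₀ + k(m_frag − q·m_H). Average
atomic masses are an embedded table (2021 standard atomic weights,
conventional values for interval elements: H 1.008, C 12.011, N 14.007,
O 15.999, S 32.06, Cl 35.45, P 30.973761998, Pt 195.084, …); the test
suite cross-checks them against an independent library but the
implementation never depends on one. For PtC21H15N3 with q = 2 the
per-fragment shift is +502.44 Da.

**Assignment.** Candidate compositions enumerate k = 0…k_max fragments
× {none, H3PO4, H2SO4}; the smallest |observed − predicted| within the
peak-list tolerance (default 1.5 Da, matching intact-protein
deconvolution accuracy) wins. When two candidates are both within
tolerance *and* within 0.5 Da of each other the peak is flagged
`isobaric-ambiguity` and all contenders are reported — sulphuric
(98.07 Da) and phosphoric (97.99 Da) acid are the canonical case.
Unmatched peaks are flagged `unassigned`, never force-fitted.

**Deconvolution.** For synthetic centroided envelopes: candidate neutral
masses on a 0.25 Da grid are scored by the summed intensity of raw peaks
within 0.75 m/z of (M + z·m_p)/z over z = 8–14; candidates must match
≥ 3 distinct charge states, contiguous accepted grid runs collapse to
one species, and each species is refined by the intensity-weighted mean
of its matched peaks' implied masses. This is deliberately minimal — see
limitations.

## 4. Synthetic data (`metallobind.simulate`)

Defaults reproduce the titration/DSC/MS working conditions of a typical
metallodrug–protein study: 1.3×10⁻⁴ M complex titrated with 2.0×10⁻³ M
protein stock in 8.2 µL additions (initial cell volume 1.15 mL); DSC at
2×10⁻⁴ M protein, 0.5 °C/min, 20–95 °C; noise levels σ_A = 0.002 AU,
DSC 1% of peak height, MS 2% relative intensity. All randomness flows
from one integer seed through `numpy.random.default_rng`; σ = 0 output
is seed-independent and simulator output is byte-reproducible per seed.

What the generators emulate:

* titration — exact n-site mass-action equilibrium, per-addition
  dilution bookkeeping, Beer–Lambert spectra from equal-width Gaussian
  free/bound bands (two-state mixing then has an exact isosbestic
  crossing, computable in closed form), additive Gaussian absorbance
  noise, a matched reference cell (protein absorbs nothing);
* DSC — single or weighted mixtures of two-state endotherms on a 0.1 K
  grid;
* ESI — one centroid per species and charge with a Gaussian
  charge-state profile, sub-half-FWHM centroids merged
  intensity-weighted, acquisition-window clipping, multiplicative
  intensity noise.

What they deliberately do **not** emulate: baseline drift and lamp noise
correlated across wavelengths, protein absorbance bleed-through,
irreversible/kinetically controlled unfolding, scan-rate effects,
isotopic fine structure, profile-mode peak shapes, detector saturation,
and adduct heterogeneity beyond the configured species list. The
generating model equals the fitted model, so recovery tests are sharp
correctness checks of the estimators — not evidence of robustness to
model misspecification.

## 5. Limitations

* The linearized estimators assume the analysis wavelength has constant
  Δε over the titration (single set of equivalent, non-interacting
  sites; no spectroscopically distinct intermediates).
* Jackknife SEs undercover somewhat for strongly nonlinear ratios (the
  Scatchard K at n = 0.5 shows per-seed coverage just below 80%); treat
  ±2 SE as approximate, and prefer the nonlinear oracle's errors when
  the data support it.
* The two-state DSC fit has no irreversibility model; `FAILED` status
  distinguishes "not a single two-state species" but cannot identify
  the mixture composition.
* The envelope deconvolver assumes centroided data, a known charge
  range and resolved species; it is a bookkeeping reference, not a
  replacement for production deconvolution software.
* Average (not isotope-resolved) masses throughout; predictions carry
  the ~0.1 Da uncertainty of the conventional atomic weights of S and
  Cl-containing species.
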