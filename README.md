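# metallobind

Thermodynamic and mass-spectrometric analysis of metallodrug–protein
binding: UV-Vis titration binding constants, two-state DSC unfolding
thermodynamics, and intact-protein ESI-MS adduct assignment — plus
synthetic-data generators with known ground truth for every stage.

## The scientific problem

Cationic Pt(II) complexes (cisplatin analogues such as
[Pt(4'-phenylterpyridine)X]⁺) bind model proteins like hen egg-white
lysozyme and ribonuclease A. Characterizing that interaction takes three
independent instruments, each with its own small-but-fiddly numerical
pipeline:

1. **Differential UV-Vis titration.** Adding protein to the complex
   perturbs its MLCT band (hypochromism). The differential absorbance
   ΔA at an analysis wavelength tracks the bound fraction; mass-action
   algebra turns ΔA(C_protein) into the association constant *K* and the
   molar absorptivity change Δε. Two exact linearizations are
   implemented — an iterative double-reciprocal estimator for 1:1
   binding and a Scatchard transform for *n* independent equivalent
   sites — together with a direct nonlinear fit that serves as an
   independent cross-check.
2. **Differential scanning calorimetry.** The excess heat capacity
   Cp,exc(T) of the protein (± bound complex) yields the denaturation
   temperature T_d, the calorimetric enthalpy ΔH_cal (peak area), the
   van't Hoff enthalpy ΔH_vH (two-state fit), and ΔS = ΔH/T_d. A fit
   whose RMS residual exceeds 5% of the peak height is declared FAILED —
   the signature of a mixture of differently liganded populations.
3. **Intact-protein ESI-MS.** A bound q+ metal fragment shifts the
   deconvolved neutral mass by (fragment mass − q·m_H), because q protons
   are displaced to keep the adduct neutral. The package predicts adduct
   masses from molecular formulas, deconvolves charge envelopes, and
   assigns peaks — flagging the classic isobaric +98 Da
   sulphuric/phosphoric acid artefact instead of guessing.

## Worked example

```python
from metallobind import (simulate_titration, build_isotherm,
                         fit_eq2_iterative, nls_oracle_fit)

series = simulate_titration(k=5e3, delta_eps=-5000.0, sigma_a=0.002, seed=1)
iso = build_isotherm(series, lambda_star=378.0)
fit = fit_eq2_iterative(iso)
print(f"K = {fit.k:,.0f} +/- {fit.k_stderr:,.0f} 1/M in {fit.n_iter} iterations")
print(f"delta_eps = {fit.delta_eps:,.0f} 1/M/cm")
print(f"oracle K = {nls_oracle_fit(iso).k:,.0f} 1/M")
```

prints (truth: K = 5,000 M⁻¹, Δε = −5,000 M⁻¹cm⁻¹):

```
K = 4,395 +/- 838 1/M in 7 iterations
delta_eps = -5,349 1/M/cm
oracle K = 5,512 1/M
```

On noiseless data both estimators recover K exactly (they agree to better
than 0.1% for K between 10² and 10⁵ M⁻¹); at realistic noise the ±2 SE
interval covers the truth in ≥ 80% of seeds. The `examples/` directory
holds one narrative script per capability:

```sh
python examples/binding_titration.py   # K, delta_eps, Scatchard n and K'
python examples/dsc_unfolding.py       # T_d, dH_cal, dH_vH, mixture FAILED
python examples/adduct_assignment.py   # predict -> simulate -> deconvolve -> assign
```

The adduct example predicts the platinated-protein mass roster from the
PtC21H15N3 fragment formula (fragment +502.44 Da per binding event):
ribonuclease A 13,682 → 14,184.4 (mono) / 14,686.9 (bis) Da, lysozyme
14,304 → 14,806.4 Da, and the phosphate artefact at 13,780.0 Da, which
the assignment engine flags as isobaric with sulphate.

A thin CLI mirrors the three-instrument workflow:

```sh
metallobind simulate titration --seed 3 --outdir run/
metallobind titrate fit run/titration.csv run/titration_config.json --out run/fit.json
metallobind dsc fit thermogram.csv
metallobind adducts assign peaks.csv fragments.json --m0 13682
```

Exit codes: 0 success, 2 malformed input, 3 fit failure.

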