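"""Predict and assign protein-metallodrug adduct masses from ESI-MS data.

A [Pt(4'-phenylterpyridine)]2+ fragment (the species left after loss of
the labile halide) binds ribonuclease A (13,682 Da) and lysozyme
(14,304 Da), displacing two protons per fragment.  We predict the adduct
masses from the molecular formula, simulate a charge envelope, deconvolve
it back to neutral masses, and assign the peaks - including the isobaric
+98 Da sulphate/phosphate purification artefact.
"""

import numpy as np

from metallobind import (
    FragmentSpec,
    NeutralPeakList,
    assign_adducts,
    average_mass,
    deconvolve_envelope,
    predict_adduct_mass,
    simulate_esi_spectrum,
)

RNASE_A, HEWL = 13682.0, 14304.0
frag = FragmentSpec(label="Pt(terpy-Ph)", formula="PtC21H15N3", charge=2)

print(f"fragment formula PtC21H15N3: average mass "
      f"{average_mass(frag.formula):.2f} Da")
print(f"mass shift per bound fragment (2 protons displaced): "
      f"{frag.mass_shift:+.2f} Da\n")

for name, m0, k in [("RNase A + 1", RNASE_A, 1), ("RNase A + 2", RNASE_A, 2),
                    ("HEWL    + 1", HEWL, 1)]:
    print(f"{name}: predicted {predict_adduct_mass(m0, frag, k):.1f} Da")
print(f"RNase A + H3PO4: predicted {RNASE_A + average_mass('H3PO4'):.1f} Da")

# --- simulate an envelope of the platinated sample and deconvolve it -------
species = [(RNASE_A, 1.0),
           (RNASE_A + average_mass("H3PO4"), 0.35),
           (predict_adduct_mass(RNASE_A, frag, 1), 0.6),
           (predict_adduct_mass(RNASE_A, frag, 2), 0.25)]
raw = simulate_esi_spectrum(species, sigma_rel=0.02, seed=1)
print(f"\nsimulated envelope: {raw.shape[0]} centroids, m/z "
      f"{raw[0, 0]:.0f}-{raw[-1, 0]:.0f}")

peaks = deconvolve_envelope(raw)
print("deconvolved neutral masses:",
      ", ".join(f"{m:.1f}" for m in peaks.masses_da))

# --- assign each neutral peak to a composition -----------------------------
assignments = assign_adducts(
    NeutralPeakList(peaks.masses_da, peaks.intensities, tolerance_da=1.5),
    m0=RNASE_A, fragments=[frag], k_max=2)
print("\nassignments:")
for a in assignments:
    alt = (" | also: " + ", ".join(r.composition for r in a.ambiguous_with)
           if a.ambiguous_with else "")
    flags = f"  [{';'.join(a.flags)}]" if a.flags else ""
    print(f"  {a.observed_da:9.1f} Da -> {a.composition:<22s} "
          f"(err {a.error_da:+.2f} Da){flags}{alt}")
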