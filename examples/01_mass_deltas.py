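"""Accurate-mass arithmetic: from formulas to ions, and back from deltas.

Computes the protonated and fragment-cation m/z values of fentanyl-class
ions, then decomposes the precursor mass differences observed between
network nodes into candidate elemental changes.
"""

from molnet import decompose_delta, fragment_mz, parse_formula, protonated_mz

print("Protonated molecules [M+H]+")
for formula in ("C22H28N2O", "C19H24N2", "C24H23NO"):
    print(f"  {formula:>10} -> {protonated_mz(parse_formula(formula)):.4f} Th")

print("Fragment cations (electron-corrected)")
for cation in ("C13H18N", "C8H9", "C14H20N"):
    print(f"  {cation:>10} -> {fragment_mz(parse_formula(cation)):.4f} Th")

print("Observed node deltas decomposed at 5 mDa")
for delta in (94.005, 17.991, 28.032, 51.995, 122.037):
    cands = decompose_delta(delta, tol=0.005)
    top = ", ".join(f"{c.formula} ({c.error*1e3:+.1f} mDa)" for c in cands[:3])
    print(f"  {delta:8.3f} Da -> {top}")

# The 94.005 Da gap between the m/z 393.197 seizure node and despropionyl
# para-fluorofentanyl reads as a furanoyl attachment (C5H2O2); 17.991 Da
# from furanylfentanyl is a fluorine-for-hydrogen substitution.
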