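"""Locate the deuterium on the SQ ring from tandem-MS shift observations.

Hydrolysis of an SQ glycoside in D2O by an NAD+-dependent SQase leaves one
non-exchangeable D on the sugar.  The [M−H]⁻ ion shifts from nominal m/z 243
to 244; the fragments at 123/153/183 do not shift (so the D is not on any
carbon they cover, C3–C6); and 244→207 loses HOD across C2–C3, erasing the
shift.  Constraint propagation over these observations pins the label.
"""

from sqgsuite import msfrag as mf

print(f"SQ [M-H]-           nominal m/z = {mf.mass(mf.SQ_MH):.0f}")
labeled = mf.deuterate(mf.SQ_MH, 1)
print(f"after 1 D           nominal m/z = {mf.mass(labeled):.0f}")
ion = mf.FragmentIon("244", mf.CARBONS, formula=labeled)
product = mf.apply_losses(ion, [mf.HOD, mf.WATER])
print(f"244 - HOD - H2O     nominal m/z = {product.nominal_mz:.0f}")

result = mf.infer_label_position(mf.SQ_FRAGMENT_TABLE, mf.SQ_D2O_OBSERVATIONS)
carbons = ", ".join(f"C{c}" for c in sorted(result.feasible))
print(f"\nfeasible label positions: {{{carbons}}}  (status: {result.status})")
print("A single feasible carbon, C2, is the signature of the oxidoreductive "
      "mechanism: transient C3 oxidation, elimination, and re-hydration "
      "deposit solvent deuterium at C2.")
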