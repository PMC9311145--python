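"""δ¹³C bookkeeping: scale conversion and FAME derivative correction.

A labelled residue at 6.7 atom % ¹³C sits thousands of permil above the
natural-abundance background, which is what makes two-pool mixing
tractable.  Methanolysis adds one methanol carbon per fatty acid, so
the measured FAME δ must be corrected back to the lipid before any
mixing arithmetic.
"""

from plfasip import (
    atom_fraction_to_delta,
    correct_fame_to_plfa,
    delta_to_atom_fraction,
)

print("natural soil background: δ¹³C = -28 ‰ ->",
      f"atom fraction {delta_to_atom_fraction(-28.0):.6f}")
print("labelled buckwheat residue: 6.7 atom % ->",
      f"δ¹³C = {atom_fraction_to_delta(0.067):.1f} ‰")

# a 16:0 methyl ester measured at +100 ‰ with methanol at -40 ‰
delta_fame, n_carbon, delta_methanol = 100.0, 16, -40.0
delta_plfa = correct_fame_to_plfa(delta_fame, n_carbon, delta_methanol)
print(f"FAME δ {delta_fame:+.1f} ‰ (16:0, methanol {delta_methanol:+.1f} ‰) ->",
      f"PLFA δ {delta_plfa:+.2f} ‰")
print("the correction amplifies the lipid-methanol offset by (n+1)/n =",
      f"{(n_carbon + 1) / n_carbon:.4f}")
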