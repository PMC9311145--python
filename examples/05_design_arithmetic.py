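"""Design-table arithmetic: added tracer mass and blended residue C:N.

Every amended treatment receives 1 mg C g⁻¹ soil; labelled treatments
supply 25 % of it as ¹³C-labelled residue, so the added ¹³C mass is
rate × 0.25 × the residue's atom fraction.  Mixture C:N is the ratio of
total C to total N of the blend — the C-share-weighted harmonic mean of
the component ratios, not their arithmetic mean.
"""

from plfasip import added_13c, default_design, mixture_cn

designs = {d.treatment_id: d for d in default_design()}
print("added ¹³C (mg ¹³C g⁻¹ soil):")
for tid in ("NB", "NC", "NR", "NS"):
    d = designs[tid]
    atom = d.residue_atom_fraction[d.labelled_species]
    print(f"  {tid} ({d.labelled_species:10s} {100 * atom:.1f} atom %): "
          f"{added_13c(d):.4f}")

print("\nblended residue C:N of the mixture treatments:")
for tid in ("MB", "MC", "MR", "MS"):
    print(f"  {tid}: {mixture_cn(designs[tid]):.1f}")
print("(components span C:N 9-32; the blend lands near 17)")
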