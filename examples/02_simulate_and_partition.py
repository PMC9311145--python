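"""Simulate the 13-treatment microcosm experiment and partition the carbon.

The preset generates GC-FID concentrations and GC-C-IRMS δ values for
4 pure, 4 non-mixture, 4 mixture and 1 control treatment (4 replicates
each), then the partition pipeline attributes every biomarker's carbon
to the crop residues, primed soil organic matter, or the pre-existing
(control) biomass.  The printed treatment means are μg C per g dry
soil; MIX rows are assembled replicate-wise from the four labelled
mixture sub-treatments.
"""

from plfasip import paper_like_preset, partition_experiment, simulate_experiment

config = paper_like_preset(seed=42)
sim = simulate_experiment(config)
print(f"simulated {sim.measurements['sample_id'].nunique()} samples × "
      f"{sim.measurements['biomarker'].nunique()} biomarkers")

tables = partition_experiment(sim.measurements, sim.designs, config.constants())
totals = (
    tables.replicate.query("level == 'total'")
    .groupby("treatment_id")[["c_total", "c_baseline", "c_plant", "c_som"]]
    .mean()
    .round(2)
)
print("\ntreatment means (μg C g⁻¹ soil):")
print(totals.to_string())

print("\nmixture plant-derived C by contributing species (replicate means):")
print(tables.mixture_breakdown.groupby("species")["c_plant"].mean().round(3).to_string())
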