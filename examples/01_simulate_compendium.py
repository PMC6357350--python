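"""Generate a synthetic multi-study expression compendium.

Builds the default compendium — ten tissue sites across two reference
studies, one tumor cohort with matched adjacent normals, known tissue /
batch / disease effects — and prints its composition.  The printed counts
show what every downstream example works with.
"""

from refnorm import SimulationConfig, simulate_compendium, write_compendium

config = SimulationConfig(seed=1)
counts, meta, truth = simulate_compendium(config)

print(f"genes x samples: {counts.n_genes} x {counts.n_samples}")
print(meta.table.groupby(["sample_type", "study"]).size().to_string())
print(f"\ntissue sites: {sorted(meta.table['site'].unique())}")
print(f"true DE genes: {len(truth.de_genes)} "
      f"({(truth.de_genes['direction'] == 'up').sum()} up / "
      f"{(truth.de_genes['direction'] == 'down').sum()} down)")

write_compendium(counts, meta, truth, "scratch/example_compendium")
print("\nwrote TSVs to scratch/example_compendium/")
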