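"""Residence, RT-clade, and taxon profiles of candidate systems, plus SVG
gene maps.

A real defense system should be predominantly cellular or predominantly
viral, carry a single RT clade, and show taxon-specific clade preferences.
"""

from dgrscout.composition import assign_compositions, select_compositions
from dgrscout.icity import run_icity, select_pfams
from dgrscout.profiles import (
    clade_profile, export_gene_maps, residence_profile, taxon_profile,
)
from dgrscout.simulate import SimConfig, simulate_dataset

sim = simulate_dataset(
    SimConfig(n_contigs=300, seed=17, with_sequences=False,
              p_immune_colocalization=0.95, p_viral=0.25, taxon_clade_bias=0.9)
)
table = run_icity(sim.dataset, seed=18)
comps = select_compositions(
    assign_compositions(sim.dataset, select_pfams(table), sim.immune_catalog)
)

comp = comps[0]
res = residence_profile(comp, sim.dataset)
print(f"composition: {comp.label()}")
print(f"residence: {res.counts['cellular']} cellular / {res.counts['viral']} viral"
      f" -> minority fraction {res.minority_fraction:.2f}")

cla = clade_profile(comp)
print(f"modal RT clade fraction: {cla.modal_fraction:.2f} "
      f"(single clade: {cla.single_clade})")

_, matrix = taxon_profile(comps, sim.dataset)
print("\nclade-by-taxon proportions (rows sum to 1):")
print(matrix.round(2).to_string(index=False))

paths = export_gene_maps(comps, sim.dataset, "scratch_example_maps")
print(f"\nwrote {len(paths)} SVG gene map(s), e.g. {paths[0]}")
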