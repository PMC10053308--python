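"""Generate a small synthetic dataset of DGR-encoding contigs.

Every contig carries a planted DGR cassette (RT gene, template repeat, and
a variable repeat inside a target gene) plus an Avd-like accessory, an
immune-Pfam gene co-localized with probability 0.9, and random decoy genes.
The ground-truth table records what was planted where.
"""

from dgrscout.simulate import SimConfig, simulate_dataset

sim = simulate_dataset(SimConfig(n_contigs=25, seed=11, with_sequences=True))
ds = sim.dataset

print(f"contigs:  {ds.n_contigs}")
print(f"genes:    {len(ds.features)}")
print(f"systems:  {len(ds.systems)}")
lengths = [c.length for c in ds.contigs.values()]
print(f"lengths:  {min(lengths):,} - {max(lengths):,} bp "
      f"({sum(L > 20_000 for L in lengths)} contigs > 20 kbp)")
print(f"circular: {sum(c.is_circular for c in ds.contigs.values())}")
coloc = sim.ground_truth.immune_colocalized.mean()
print(f"immune gene within 10 kbp of the DGR on {coloc:.0%} of contigs")

paths = sim.write("scratch_example_data")
print("wrote:", ", ".join(sorted(paths)))
# The files are the exact input formats of the analysis stages: a contig
# metadata TSV, GFF3 gene calls, per-gene Pfam hits, the DGR component
# table, the immune-Pfam catalog, FASTA sequences, and ground_truth.tsv.
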