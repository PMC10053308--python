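# dgrscout

Screening annotated prokaryotic contigs for candidate defense systems
organized around **diversity-generating retroelements (DGRs)** — loci where
an error-prone reverse transcriptase (RT) copies a template repeat (TR)
into a variable repeat (VR) inside a target gene, hypermutating it. If
prokaryotes use DGRs to diversify defense proteins in advance of infection,
the genomic neighborhoods of DGR components should be enriched for
immunity-associated protein families, arranged in conserved operon-like
modules. `dgrscout` finds and characterizes such candidates.

It is a library for people who already have gene calls, Pfam assignments,
and DGR component annotations (plus a catalog of "immune" Pfams), and want
a tested, reproducible implementation of the screen; a synthetic-data
generator with full ground truth makes every stage testable without any
download.

## What it computes

**Icity co-localization score.** For each protein cluster (a
version-stripped Pfam family; VR-hosting proteins form a separate cluster)
the score is

    icity = w′ / w

where *w* is the redundancy-weighted count of the family's genes in the
dataset and *w′* the weighted count of those lying within 10 kbp of an RT
or VR bait gene. Duplicated loci are dereplicated by neighborhood content
(k identical neighborhoods ⇒ member weight 1/k). Scoring is repeated over
seeded 80% contig subsamples until two consecutive runs reveal no new
family with score > 0.7, and families exceeding 0.7 in **all** runs are
kept.

**Compositions and arrangements.** Loci are grouped by their set of
selected families ("compositions"); only compositions with at least one
immune Pfam, more than 20 occurrences, and ≥ 4 occurrences on contigs
> 20 kbp survive. For each, gene order/orientation is canonicalized (n
genes admit 2^(n−1)·n! distinguishable arrangements — 4 for n=2, 24 for
n=3) and the modal arrangement fraction measures conservation.

**Codon-usage HGT screen.** Per contig, Wright's effective number of
codons (Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ ∈ [20, 61]) is computed for
every ORF > 360 nt in the system region (±10 kbp) and in an equal-sized
antipodal control region (omitted when the regions come within 20 kbp); a
two-sample Kolmogorov–Smirnov test at α = 0.05 flags codon-usage
discordance, the signature of recent horizontal transfer.

**Profiles.** Residence (cellular vs. viral) minority fractions, RT-clade
purity, taxon distributions, and SVG gene maps per candidate system.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Score a simulated dataset in which the immune family PF01797 was planted
within 10 kbp of the DGR on 90% of contigs (`examples/02_icity_screen.py`):

```python
from dgrscout.icity import run_icity, select_pfams
from dgrscout.simulate import SimConfig, simulate_dataset

sim = simulate_dataset(SimConfig(n_contigs=150, seed=4, with_sequences=False,
                                 p_immune_colocalization=0.9))
table = run_icity(sim.dataset, window_bp=10_000, threshold=0.7,
                  subsample_fraction=0.8, seed=8)
```

Output:

```
converged after 2 runs, 34 clusters

cluster          mean icity
PF00078          1.000
PF05635          1.000
VR.PF01833       1.000
PF01797          0.952
PF90011          0.585
PF90014          0.574

strict selection (>0.7 in every run):  ['PF00078', 'PF01797', 'PF05635', 'VR.PF01833']
```

The four planted cassette families (RT, Avd-like accessory, VR-hosting
target, immune) score at or near 1 — the immune family's 0.95 mean matches
its planting probability — while uniformly placed decoy families (PF9xxxx)
sit far below the 0.7 threshold and fail selection. Downstream
(`examples/04_codon_bias_screen.py`), a planted codon-shifted island turns
into `proportion_significant = 1.0` with mean Nc ≈ 38 in system regions
vs. ≈ 49 in controls.

The other scripts in `examples/` walk through dataset simulation,
composition/arrangement analysis, profiling with gene maps, and the full
pipeline (`run_all`), which is also available from the shell:

```bash
dgrscout run-all --config pipeline.yaml --seed 42 --out OUT
```

Re-running any stage with the same config and seed reproduces every output
file byte-identically.

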