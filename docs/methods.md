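# Methods

`dgrscout` implements a guilt-by-association screen for candidate
prokaryotic defense systems organized around diversity-generating
retroelements (DGRs), together with the downstream analyses that separate
plausible functional systems from co-localization noise: composition
selection, gene-arrangement conservation, a codon-usage screen for recent
horizontal transfer, and residence/clade/taxon profiling. This note
describes the models and procedures, the parameters that matter, what the
bundled simulator does and does not emulate, and the numerical choices made
where the design was open.

## The co-localization model (Icity)

A DGR locus is annotated by its reverse transcriptase (RT) gene, template
repeat (TR), and one or more variable repeats (VR), each VR inside a host
("target") gene. The screen asks, for every protein cluster in a dataset,
what fraction of its members sit within a fixed window of a DGR component.
Clusters are version-stripped Pfam families, with VR-hosting proteins split
into their own cluster (`VR.PFxxxxx`): a VR-carrying member of a family is
functionally a different object from its non-VR peers, and merging them
would dilute both signals.

For a bait gene b (an RT gene or a VR host gene), the neighborhood is the
bait's span extended by D bp on each side (default D = 10,000). A gene is a
member iff its interval overlaps the window by at least 1 bp; on circular
contigs windows and intervals wrap the origin, and all interval arithmetic
is modular. The bait is always a member of its own neighborhood, so a
bait's own family scores 1 — the intended boundary behavior, since RT genes
are by construction perfectly co-localized with DGRs.

Datasets assembled from public archives over-represent some loci almost
verbatim. To keep one heavily deposited locus from dominating the
statistic, neighborhoods are dereplicated by *fingerprint*: the ordered
cluster content of the neighborhood. If k neighborhoods share a
fingerprint, every member gene of those neighborhoods carries weight 1/k
(a gene in several neighborhoods takes the weight of its first containing
neighborhood in a deterministic sort; genes outside all neighborhoods keep
weight 1). The Icity score of cluster C is then

    icity(C) = w' / w,
    w  = sum of weights of all genes carrying C,
    w' = sum of weights of those genes inside >= 1 neighborhood,

a number in [0, 1], reaching 1 only when every (weighted) occurrence of the
family in the dataset is DGR-adjacent.

### The multi-run protocol

One run: draw a seeded random subsample of the contigs without replacement
(default fraction 0.8), score every cluster against RT baits alone and VR
baits alone, and keep the per-cluster maximum of the two. Runs repeat until
a run (after a 2-run minimum, 25-run cap) reveals no cluster newly
exceeding the threshold (default 0.7) relative to all earlier runs — i.e.
until two consecutive runs agree on the above-threshold set. The table
reports all per-run scores and their mean. With subsample fraction 1.0
every run is identical and the protocol is deterministic with exactly two
runs, which the exact tests exploit.

Selection is by strict inequality: *strict* mode requires score > 0.7 in
every recorded run, *lenient* mode in at least one. A cluster entirely
absent from a run's subsample records no score for that run; selection
quantifies over recorded scores. Rare clusters are therefore judged on the
runs that could see them rather than auto-failed, at the cost of fewer
effective replicates for them.

## Compositions and arrangement conservation

Per DGR locus (one per DGR system; a contig with two systems contributes
two loci) the *composition* is the set of strictly selected clusters
present in the locus's neighborhood (union of its RT and VR windows). Loci
whose composition contains no immune Pfam — no family from the provided
catalog of defense-associated families — are dropped. Identical
compositions merge; a composition survives only if it occurs on more than
20 loci, of which at least 4 lie on contigs longer than 20 kbp (short
metagenomic contigs truncate neighborhoods and would otherwise flood the
composition list with fragments of larger systems).

n distinct genes can be ordered n! ways with 2^n strand choices; because a
locus can be read in either direction, arrangements come in equivalent
pairs, leaving 2^(n−1)·n! distinguishable classes (4 for n = 2, 24 for
n = 3). The canonical form of a locus's gene order is the lexicographic
minimum of the signature — the left-to-right list of (family, VR flag,
strand) restricted to the composition — and its reversal with strands
flipped. Reverse-complementing a contig therefore never changes the class.
Loci spanning a circular origin are read starting at the RT window's start.
A composition's *modal fraction* is the share of its loci in the most
common class; functional systems are expected near 1, scrambled neighbors
near the uniform floor.

Genes with several composition Pfams contribute one signature element per
family in accession order; duplicated families appear once per occurrence
in positional order, so duplicates still canonicalize deterministically.

## Codon-usage screen

A recently transferred module keeps its donor's codon usage. Per ORF
longer than 360 nt, codon usage bias is summarized by Wright's effective
number of codons,

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

where Fk is the mean, over observed amino-acid families of synonymous
degeneracy k, of the unbiased homozygosity estimate
F̂ = (n·Σp_i² − 1)/(n − 1) (n codons observed in the family, p_i their
frequencies; families with n < 2 are skipped). Nc runs from 20 (one codon
per family) to 61 (uniform synonymous usage); results are capped to that
range. If the single 3-fold family (Ile) is unobserved, F3 is imputed as
(F2+F4)/2 — Wright's own fallback; any other missing class uses the mean
of the available class means. The three 6-fold families keep their own
3/F6 term rather than a 2+4 split, which is what makes the uniform limit
exactly 61. Stop codons and codons containing ambiguous bases are dropped.

Per contig, the *system region* is the DGR core span (RT gene, TR, VR
hosts) extended ±E (default 10,000 bp); the *control region* has identical
length with its midpoint half the contig length away — the most distant
point under the circularity assumption. On linear contigs the control is
shifted to the farthest in-bounds position. Contigs whose two regions come
closer than G_min = 20,000 bp (or whose system region exceeds half the
contig) are omitted with a logged reason. ORFs belong to the region
containing their midpoint. The per-ORF Nc samples of the two regions are
compared by a two-sided two-sample Kolmogorov–Smirnov test (scipy,
asymptotic p); a contig is significant at α = 0.05, with no
multiple-testing correction. Samples smaller than 3 per side are
untestable and, like omitted contigs, leave the denominator of the
per-composition significant fraction.

## Residence, clade, and taxon profiles

Residence (cellular/viral), RT clade (1–6, input metadata), and taxon are
summarized per composition: the minority residence fraction
min(cellular, viral)/(cellular+viral), the modal clade fraction and a
single-clade flag, and a clade-by-taxon proportion matrix whose rows sum
to 1 over known clades. Unknown labels never enter denominators and are
reported separately. Gene maps are emitted as deterministic SVG: arrows by
strand, RT in white, same-family genes sharing a color, VR hosts labeled.

## The synthetic-data generator

The simulator produces the statistical structure the analysis assumes —
and is the package's test bed, not a model of DGR biology:

* **Contig lengths**: log-normal with mode 3 kbp (σ = 1.2), truncated to
  3–200 kbp, with an explicit fraction (default 0.5) conditioned to exceed
  20 kbp; topology circular with probability 0.5. Lengths too short for
  their cassette are resampled with a logged warning.
* **Cassette**: each contig carries one DGR locus — immune gene, Avd-like
  accessory (PF05635), RT (PF00078), and VR-hosting target (PF01833), with
  the TR placed after the RT gene and the VR inside the target. The
  canonical order and all-plus strands are kept with probability
  `arrangement_conservation` (default 0.98) and scrambled uniformly
  otherwise.
* **Immune placement**: inside the cassette with probability
  `p_immune_colocalization`, else uniformly outside both bait windows;
  when a short contig leaves no room outside, the gene is omitted and the
  ground truth records it.
* **Decoys**: Poisson-placed background genes (default 0.3/kbp; 30 decoy
  families; lengths 300–2,400 nt so some ORFs fail the 360 nt filter),
  positioned with no DGR association.
* **Sequences**: genes are sampled codon-by-codon from a background usage
  table (within-family weights 1, 1/2, 1/3, …). Genes inside the island
  (cassette ± 10 kbp) use a table interpolated by `codon_shift_delta`
  toward each family's least-used background codon, so delta = 0 is an
  exact null and delta = 1 collapses each family to one codon. VR
  sequences are TR copies substituted at adenine positions — qualitative
  DGR realism only; no retrohoming dynamics, no phylogenetic sequence
  evolution.
* **Labels**: viral residence with probability 0.25; taxa from a fixed
  five-name vocabulary; RT clade drawn from the taxon's fixed preferred
  pair with probability `taxon_clade_bias` (default 0.8), else from the
  global clade weights.

Because decoys are uniform and every contig carries a DGR, a decoy family's
Icity settles near the fraction of the dataset covered by bait windows
(well below 0.7 at the default length mix), while planted cassette
families approach their planting probability — this is the separation the
recovery tests quantify. What passing tests on this simulator do *not*
show: robustness to mis-annotated gene calls, to homology between decoy
families, to multiple DGR systems per contig, or to real phylogenetic
correlation between loci; fingerprint dereplication is exercised only by
construction, not by realistic near-duplicate sequences.

## Numerical choices and problem sizes

Tolerances on stochastic checks are binomial: recovered proportions are
required to sit within 2–3 standard errors of the planted value at the
stated sample size. The calibration and recovery analyses use 200-contig
datasets (500 loci for arrangement conservation); the codon-usage
calibration draws 90–140 kbp contigs at 0.6 decoy genes/kbp so each region
holds ~14 testable ORFs, enough for the discrete two-sample KS statistic
to have attainable levels near 0.05 — with far fewer ORFs per region the
test's discreteness makes it visibly conservative. Ties in modal
arrangement and modal clade break toward the lexicographically smallest
signature/label. Empty neighborhoods, all-unknown labels, and
compositions with zero testable contigs yield explicit NA/empty outputs
rather than errors. Subsamples that contain no DGR contig are redrawn with
a warning.

## Known limitations

* The redundancy weighting and subsampling scheme is this package's own
  documented substitute for the unpublished internals of the original
  co-localization protocol; scores are comparable within a dataset, not
  across tools.
* RT clades are input metadata; no phylogenetic inference is performed.
* The KS comparison treats per-ORF Nc values as exchangeable samples;
  gene-length variation within a region is ignored.
* Linear contigs break the circularity assumption behind the antipodal
  control; the farthest in-bounds placement is a compromise and is logged
  per contig.
* No multiple-testing correction is applied across contigs or
  compositions in the codon-usage screen (by design, α as printed).
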