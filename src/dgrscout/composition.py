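"""Pfam compositions of DGR loci and gene-arrangement conservation.

A *composition* is the set of high-Icity clusters found in the +/- 10 kbp
neighborhood of one DGR locus; only loci whose composition contains at least
one immune Pfam are kept. Compositions recurring across many contigs are the
candidate defense systems.

For a functional system one expects the member genes to keep a conserved
order and orientation. ``n`` distinct genes admit ``n!`` orders times
``2^n`` strand choices, halved because a locus can be read in either
direction: ``2^(n-1) * n!`` distinguishable arrangements (4 for n=2, 24 for
n=3). ``canonical_signature`` implements that halving: a locus signature and
its reverse-with-strands-flipped image map to the same canonical form, so
reverse-complementing a contig never changes the arrangement class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Optional

import pandas as pd

from .dataset import Dataset
from .icity import ClusterKey, Neighborhood, cluster_keys_of, extract_neighborhoods
from .model import DgrSystem, ImmuneCatalog

DEFAULT_MIN_OCCURRENCES = 20  # strict: keep if n_occurrences > 20
DEFAULT_MIN_LONG = 4
DEFAULT_LONG_BP = 20_000

#: One signature element: (accession, vr_flag, strand)
SigElement = tuple[str, bool, str]
Signature = tuple[SigElement, ...]


@dataclass
class Locus:
    """One DGR system with its neighborhood gene content."""

    system: DgrSystem
    member_gene_ids: list[str]  # positional order along the (rotated) locus
    key: frozenset[ClusterKey] = frozenset()


@dataclass
class Composition:
    """A recurring Pfam composition with its member loci."""

    key: frozenset[ClusterKey]
    member_loci: list[Locus] = field(default_factory=list)
    n_occurrences: int = 0
    n_long_contigs: int = 0

    def immune_members(self, catalog: ImmuneCatalog) -> set[ClusterKey]:
        return {k for k in self.key if k.accession in catalog}

    def label(self) -> str:
        return "+".join(sorted(k.label() for k in self.key))


def possible_arrangements(n: int) -> int:
    """Number of distinguishable arrangements of ``n`` distinct genes:
    ``2^(n-1) * n!`` (orders x strands, halved for reading direction)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2 ** (n - 1) * factorial(n)


def _flip(signature: Signature) -> Signature:
    flip = {"+": "-", "-": "+"}
    return tuple(
        (acc, vr, flip[strand]) for acc, vr, strand in reversed(signature)
    )


def canonical_signature(elements: Iterable[SigElement]) -> Signature:
    """Normalize a left-to-right gene arrangement for reading direction.

    Returns the lexicographic minimum of the signature and its
    reversal-with-strand-flip, so both readings of a locus (and hence the
    reverse complement of the contig) give one canonical form.
    """
    sig = tuple(elements)
    if not sig:
        raise ValueError("empty signature")
    return min(sig, _flip(sig))


def locus_signature(
    locus: Locus, dataset: Dataset, restrict_to: Optional[frozenset[ClusterKey]] = None
) -> Signature:
    """Canonical arrangement of a locus's genes, restricted to the
    composition's clusters.

    Genes are read left to right along the neighborhood; for loci spanning a
    circular origin the member list is already rotated so the reading starts
    inside the window. Genes carrying several composition Pfams contribute
    one element per Pfam, in accession order.
    """
    keys = restrict_to if restrict_to is not None else locus.key
    elements: list[SigElement] = []
    for gid in locus.member_gene_ids:
        gene = dataset.gene(gid)
        for ck in sorted(cluster_keys_of(gene)):
            if ck in keys:
                elements.append((ck.accession, ck.vr_flag, gene.strand))
    return canonical_signature(elements)


def _locus_members(
    system: DgrSystem, neighborhoods: list[Neighborhood], dataset: Dataset
) -> list[str]:
    """Union of the system's bait neighborhoods, in positional order.

    Position is measured from the RT neighborhood's window start modulo the
    contig length, which linearizes loci that span a circular origin.
    """
    nbs = [
        nb
        for nb in neighborhoods
        if (nb.bait_kind == "RT" and nb.bait_gene_id == system.rt_gene_id)
        or (nb.bait_kind == "VR" and nb.bait_gene_id in system.vr_host_gene_ids())
    ]
    if not nbs:
        return []
    members: set[str] = set()
    for nb in nbs:
        members.update(nb.member_gene_ids)
    contig = dataset.contigs[system.contig_id]
    rt_nb = next((nb for nb in nbs if nb.bait_kind == "RT"), nbs[0])
    origin = rt_nb.window[0] % contig.length if contig.is_circular else 0
    L = contig.length

    def pos(gid: str) -> tuple[int, str]:
        g = dataset.gene(gid)
        p = (g.start - origin) % L if contig.is_circular else g.start
        return (p, gid)

    return sorted(members, key=pos)


def assign_compositions(
    dataset: Dataset,
    selected: set[ClusterKey],
    catalog: ImmuneCatalog,
    window_bp: int = 10_000,
    long_bp: int = DEFAULT_LONG_BP,
    neighborhoods: Optional[list[Neighborhood]] = None,
) -> list[Composition]:
    """Group DGR loci by their selected-cluster content.

    Per locus the key is the set of selected clusters present in its
    neighborhood; loci with no immune Pfam in the key are dropped. Identical
    keys merge, accumulating occurrence and long-contig counts. One DGR
    system is one locus, so a contig with two systems contributes twice.
    """
    if neighborhoods is None:
        neighborhoods = extract_neighborhoods(dataset, window_bp)
    by_key: dict[frozenset[ClusterKey], Composition] = {}
    for system in dataset.systems:
        members = _locus_members(system, neighborhoods, dataset)
        present: set[ClusterKey] = set()
        for gid in members:
            present.update(cluster_keys_of(dataset.gene(gid)))
        key = frozenset(present & selected)
        if not any(k.accession in catalog for k in key):
            continue
        locus = Locus(system=system, member_gene_ids=members, key=key)
        comp = by_key.setdefault(key, Composition(key=key))
        comp.member_loci.append(locus)
        comp.n_occurrences += 1
        if dataset.contigs[system.contig_id].length > long_bp:
            comp.n_long_contigs += 1
    return sorted(by_key.values(), key=lambda c: (-c.n_occurrences, c.label()))


def select_compositions(
    compositions: Iterable[Composition],
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    min_long: int = DEFAULT_MIN_LONG,
) -> list[Composition]:
    """Keep compositions seen in more than ``min_occurrences`` loci of which
    at least ``min_long`` lie on long contigs."""
    return [
        c
        for c in compositions
        if c.n_occurrences > min_occurrences and c.n_long_contigs >= min_long
    ]


@dataclass
class ArrangementProfile:
    """Distribution of canonical gene arrangements within a composition."""

    key: frozenset[ClusterKey]
    counts: dict[Signature, int]
    modal_fraction: float
    modal_signature: Signature
    possible_count: int

    @property
    def n_loci(self) -> int:
        return sum(self.counts.values())


def arrangement_profile(composition: Composition, dataset: Dataset) -> ArrangementProfile:
    """Tally canonical signatures over a composition's member loci.

    ``modal_fraction`` is the share of loci carrying the most common
    arrangement; ties break toward the lexicographically smallest signature.
    """
    counts: dict[Signature, int] = {}
    for locus in composition.member_loci:
        sig = locus_signature(locus, dataset, restrict_to=composition.key)
        counts[sig] = counts.get(sig, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("composition has no member loci")
    modal_sig = min(counts, key=lambda s: (-counts[s], s))
    return ArrangementProfile(
        key=composition.key,
        counts=counts,
        modal_fraction=counts[modal_sig] / total,
        modal_signature=modal_sig,
        possible_count=possible_arrangements(len(composition.key)),
    )


# ---------------------------------------------------------------------------
# tabular export

def _sig_text(sig: Signature) -> str:
    return ",".join(
        ("VR." if vr else "") + acc + strand for acc, vr, strand in sig
    )


def compositions_frame(
    compositions: Iterable[Composition], selected: Iterable[Composition]
) -> pd.DataFrame:
    chosen = {id(c) for c in selected}
    rows = [
        {
            "composition": c.label(),
            "n_pfams": len(c.key),
            "n_occurrences": c.n_occurrences,
            "n_long": c.n_long_contigs,
            "selected": id(c) in chosen,
        }
        for c in compositions
    ]
    return pd.DataFrame(
        rows, columns=["composition", "n_pfams", "n_occurrences", "n_long", "selected"]
    )


def arrangements_frame(profiles: Iterable[ArrangementProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        total = p.n_loci
        for sig in sorted(p.counts, key=lambda s: (-p.counts[s], s)):
            rows.append(
                {
                    "composition": "+".join(sorted(k.label() for k in p.key)),
                    "signature": _sig_text(sig),
                    "count": p.counts[sig],
                    "fraction": p.counts[sig] / total,
                    "possible_count": p.possible_count,
                }
            )
    return pd.DataFrame(
        rows, columns=["composition", "signature", "count", "fraction", "possible_count"]
    )


def upset_matrix(compositions: Iterable[Composition]) -> pd.DataFrame:
    """Membership matrix (compositions x Pfam clusters) for upset-style
    subset/superset inspection."""
    comps = list(compositions)
    all_keys = sorted({k for c in comps for k in c.key})
    rows = []
    for c in comps:
        row = {"composition": c.label(), "n_occurrences": c.n_occurrences}
        for k in all_keys:
            row[k.label()] = int(k in c.key)
        rows.append(row)
    cols = ["composition", "n_occurrences"] + [k.label() for k in all_keys]
    return pd.DataFrame(rows, columns=cols)
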