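"""Core domain types for DGR neighborhood analysis.

All genomic intervals in this package are 0-based, half-open ``[start, end)``.
GFF3 input/output converts at the boundary. On circular contigs a feature may
wrap the origin; it is stored with ``start < contig.length`` and
``end > contig.length`` (coordinates are reduced modulo the contig length by
interval helpers, never at construction time).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

PFAM_ACCESSION_RE = re.compile(r"^PF\d{5}(\.\d+)?$")

RESIDENCES = ("cellular", "viral", "unknown")
TOPOLOGIES = ("linear", "circular")

#: Sentinel for an RT whose phylogenetic clade is not annotated.
CLADE_UNKNOWN = 0

#: The six major RT phylogenetic clades.
KNOWN_CLADES = (1, 2, 3, 4, 5, 6)


def strip_version(accession: str) -> str:
    """Return a Pfam accession without its version suffix.

    ``PF05635.13`` and ``PF05635`` both map to ``PF05635``. Family identity
    must never split on the Pfam release that produced the annotation.
    """
    if not PFAM_ACCESSION_RE.match(accession):
        raise ValueError(f"not a Pfam accession: {accession!r}")
    return accession.split(".", 1)[0]


@dataclass(frozen=True)
class PfamHit:
    """A single Pfam domain assignment on a protein."""

    accession: str
    evalue: float
    start_aa: Optional[int] = None
    end_aa: Optional[int] = None

    def __post_init__(self) -> None:
        if not PFAM_ACCESSION_RE.match(self.accession):
            raise ValueError(f"malformed Pfam accession: {self.accession!r}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")

    @property
    def base_accession(self) -> str:
        return self.accession.split(".", 1)[0]


@dataclass
class Contig:
    """A nucleotide sequence (replicon or metagenomic contig) with metadata.

    ``residence`` records whether the contig derives from a cellular genome or
    a viral one (prophages count as viral); ``taxon`` is an opaque label.
    Both default to ``"unknown"`` so annotation-only inputs still run.
    """

    id: str
    length: int
    topology: str = "linear"
    residence: str = "unknown"
    taxon: str = "unknown"
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id}: length must be >= 1")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"contig {self.id}: bad topology {self.topology!r}")
        if self.residence not in RESIDENCES:
            raise ValueError(f"contig {self.id}: bad residence {self.residence!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id}: sequence length {len(self.sequence)} != {self.length}"
            )

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass
class GeneFeature:
    """A protein-coding gene call on a contig.

    ``contains_vr`` flags genes hosting a DGR variable repeat; such proteins
    are treated as a separate cluster from their non-VR peers in the same
    Pfam family throughout the analysis.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    pfam_hits: list[PfamHit] = field(default_factory=list)
    contains_vr: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def base_accessions(self) -> list[str]:
        """Version-stripped accessions of this gene's hits, deduplicated,
        in order of first occurrence."""
        seen: list[str] = []
        for hit in self.pfam_hits:
            acc = hit.base_accession
            if acc not in seen:
                seen.append(acc)
        return seen


@dataclass
class DgrSystem:
    """One diversity-generating retroelement locus.

    The four essential components are the reverse transcriptase (RT), the
    template repeat (TR), and one or more variable repeats (VR), each VR
    residing inside a host protein-coding gene. ``clade`` is the RT
    phylogenetic clade (1-6) taken as input metadata, ``CLADE_UNKNOWN`` (0)
    when unannotated.
    """

    contig_id: str
    system_id: str
    rt_gene_id: str
    vr_intervals: list[tuple[int, int, str]]
    tr_interval: tuple[int, int]
    clade: int = CLADE_UNKNOWN

    def __post_init__(self) -> None:
        if self.clade != CLADE_UNKNOWN and self.clade not in KNOWN_CLADES:
            raise ValueError(f"system {self.system_id}: bad clade {self.clade}")

    def vr_host_gene_ids(self) -> list[str]:
        seen: list[str] = []
        for _, _, gid in self.vr_intervals:
            if gid not in seen:
                seen.append(gid)
        return seen


class ImmuneCatalog:
    """Catalog of Pfam families found near known prokaryotic defense systems.

    Membership tests are version-agnostic: ``PF05635.13`` matches a catalog
    entry ``PF05635``.
    """

    def __init__(self, accessions: Iterable[str]):
        stripped = {strip_version(a) for a in accessions}
        if not stripped:
            raise ValueError("immune catalog must be non-empty")
        self._accessions = frozenset(stripped)

    @property
    def accessions(self) -> frozenset[str]:
        return self._accessions

    def __contains__(self, accession: str) -> bool:
        return strip_version(accession) in self._accessions

    def __len__(self) -> int:
        return len(self._accessions)

    def __repr__(self) -> str:
        return f"ImmuneCatalog({len(self._accessions)} families)"


def validate_features(
    contigs: dict[str, Contig], features: Iterable[GeneFeature]
) -> None:
    """Check referential integrity and coordinate bounds of gene calls."""
    for f in features:
        contig = contigs.get(f.contig_id)
        if contig is None:
            raise ValueError(f"gene {f.gene_id}: unknown contig {f.contig_id!r}")
        if f.start >= contig.length:
            raise ValueError(
                f"gene {f.gene_id}: start {f.start} beyond contig length {contig.length}"
            )
        if f.end > contig.length and not contig.is_circular:
            raise ValueError(
                f"gene {f.gene_id}: end {f.end} beyond linear contig length {contig.length}"
            )
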