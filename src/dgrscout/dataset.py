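"""In-memory bundle of one annotated contig collection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Contig, DgrSystem, GeneFeature, PfamHit, validate_features
from . import io as dio


@dataclass
class Dataset:
    """Contigs, gene features, and DGR component annotations, cross-linked.

    ``assemble`` attaches Pfam hits to features and flags VR host genes; the
    icity/composition/codon-bias stages all consume this container.
    """

    contigs: dict[str, Contig]
    features: list[GeneFeature]
    systems: list[DgrSystem]
    _by_id: dict[str, GeneFeature] = field(default_factory=dict, repr=False)
    _by_contig: dict[str, list[GeneFeature]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._by_id = {f.gene_id: f for f in self.features}
        self._by_contig = {}
        for f in self.features:
            self._by_contig.setdefault(f.contig_id, []).append(f)
        for fs in self._by_contig.values():
            fs.sort(key=lambda f: (f.start, f.end, f.gene_id))

    @classmethod
    def assemble(
        cls,
        contigs: dict[str, Contig],
        features: list[GeneFeature],
        systems: list[DgrSystem],
        pfam_hits: Optional[dict[str, list[PfamHit]]] = None,
    ) -> "Dataset":
        validate_features(contigs, features)
        if pfam_hits is not None:
            dio.attach_pfam_hits(features, pfam_hits)
        by_id = {f.gene_id: f for f in features}
        for s in systems:
            if s.rt_gene_id not in by_id:
                raise ValueError(
                    f"system {s.system_id}: RT gene {s.rt_gene_id!r} not in features"
                )
            for _, _, host in s.vr_intervals:
                if host not in by_id:
                    raise ValueError(
                        f"system {s.system_id}: VR host gene {host!r} not in features"
                    )
                by_id[host].contains_vr = True
        return cls(contigs=contigs, features=features, systems=systems)

    @classmethod
    def load(
        cls,
        contig_table: str,
        gff3: str,
        pfam_tsv: str,
        dgr_tsv: str,
        fasta: Optional[str] = None,
        pfam_format: str = "tsv",
    ) -> "Dataset":
        contigs, features = dio.read_features(gff3, contig_table)
        if fasta is not None:
            dio.attach_sequences(contigs, fasta)
        hits = dio.read_pfam_hits(pfam_tsv, format=pfam_format)
        systems = dio.read_dgr_table(dgr_tsv)
        return cls.assemble(contigs, features, systems, hits)

    def gene(self, gene_id: str) -> GeneFeature:
        return self._by_id[gene_id]

    def genes_on(self, contig_id: str) -> list[GeneFeature]:
        return self._by_contig.get(contig_id, [])

    def subset(self, contig_ids: Iterable[str]) -> "Dataset":
        """Restrict to the given contigs (shares feature objects)."""
        keep = set(contig_ids)
        return Dataset(
            contigs={cid: c for cid, c in self.contigs.items() if cid in keep},
            features=[f for f in self.features if f.contig_id in keep],
            systems=[s for s in self.systems if s.contig_id in keep],
        )

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)
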