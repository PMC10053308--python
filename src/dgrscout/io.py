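"""Readers and writers for the pipeline's file formats.

Sequence data travels as FASTA (via Biopython), gene calls as GFF3 (parsed
with gffutils), Pfam assignments as hmmscan ``--domtblout`` or a simplified
3-column TSV, and every tabular stage input/output as TSV with a header row.
GFF3 coordinates (1-based inclusive) are converted to the package-internal
0-based half-open convention at this boundary and nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

from .model import (
    CLADE_UNKNOWN,
    Contig,
    DgrSystem,
    GeneFeature,
    ImmuneCatalog,
    PfamHit,
    validate_features,
)

CONTIG_COLUMNS = ["id", "length", "topology", "residence", "taxon"]


# ---------------------------------------------------------------------------
# contigs

def read_contig_table(path: str) -> dict[str, Contig]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "taxon": str})
    missing = [c for c in ("id", "length") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    contigs: dict[str, Contig] = {}
    for row in df.itertuples(index=False):
        contigs[row.id] = Contig(
            id=row.id,
            length=int(row.length),
            topology=getattr(row, "topology", "linear"),
            residence=getattr(row, "residence", "unknown"),
            taxon=str(getattr(row, "taxon", "unknown")),
        )
    return contigs


def write_contig_table(contigs: Iterable[Contig], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "id": c.id,
                "length": c.length,
                "topology": c.topology,
                "residence": c.residence,
                "taxon": c.taxon,
            }
            for c in contigs
        ],
        columns=CONTIG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def attach_sequences(contigs: dict[str, Contig], fasta_path: str) -> None:
    """Attach FASTA sequences to an existing contig table in place."""
    seqs = read_fasta(fasta_path)
    for cid, seq in seqs.items():
        if cid not in contigs:
            raise ValueError(f"FASTA sequence {cid!r} absent from contig table")
        if len(seq) != contigs[cid].length:
            raise ValueError(
                f"contig {cid}: FASTA length {len(seq)} != table length "
                f"{contigs[cid].length}"
            )
        contigs[cid].sequence = seq


# ---------------------------------------------------------------------------
# gene features (GFF3)

def read_features(
    gff3_path: str, contig_table_path: str
) -> tuple[dict[str, Contig], list[GeneFeature]]:
    """Read gene calls from GFF3 against a contig metadata table.

    Only ``gene`` and ``CDS`` records are kept; when both are present for the
    same ID the CDS wins (coordinates of the coding span). Features must
    reference contigs present in the table.
    """
    contigs = read_contig_table(contig_table_path)
    features: dict[str, GeneFeature] = {}
    if os.path.getsize(gff3_path) > 0:
        for rec in DataIterator(gff3_path):
            if rec.featuretype not in ("gene", "CDS"):
                continue
            if rec.seqid not in contigs:
                raise ValueError(
                    f"{gff3_path}: feature on unknown contig {rec.seqid!r}"
                )
            if rec.strand not in ("+", "-"):
                raise ValueError(
                    f"{gff3_path}: malformed strand {rec.strand!r} on {rec.seqid}"
                )
            ids = rec.attributes.get("ID", [])
            gene_id = ids[0] if ids else f"{rec.seqid}:{rec.start}-{rec.end}"
            feat = GeneFeature(
                gene_id=gene_id,
                contig_id=rec.seqid,
                start=rec.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=rec.end,
                strand=rec.strand,
            )
            if gene_id not in features or rec.featuretype == "CDS":
                features[gene_id] = feat
    out = list(features.values())
    validate_features(contigs, out)
    return contigs, out


def write_gff3(features: Iterable[GeneFeature], path: str, source: str = "dgrscout") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        source,
                        "CDS",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        f"ID={f.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pfam hits

def read_pfam_hits(path: str, format: str = "tsv") -> dict[str, list[PfamHit]]:
    """Parse per-protein Pfam assignments.

    ``format="domtblout"`` expects the hmmscan ``--domtblout`` dialect
    (whitespace-delimited, ``#`` comments; the query is the protein, the
    target the Pfam model, the independent per-domain e-value column 13).
    ``format="tsv"`` expects three columns ``gene_id  accession  evalue``
    with a header row. Duplicate (gene, accession) rows are retained.
    """
    hits: dict[str, list[PfamHit]] = {}
    if format == "domtblout":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 13:
                    raise ValueError(f"{path}:{lineno}: truncated domtblout row")
                try:
                    accession = parts[1]
                    gene_id = parts[3]
                    evalue = float(parts[12])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparsable row") from exc
                hits.setdefault(gene_id, []).append(PfamHit(accession, evalue))
    elif format == "tsv":
        with open(path) as fh:
            header = fh.readline()
            if header.strip() and not header.lower().startswith("gene_id"):
                raise ValueError(f"{path}:1: expected header 'gene_id\\taccession\\tevalue'")
            for lineno, line in enumerate(fh, 2):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                try:
                    hits.setdefault(parts[0], []).append(
                        PfamHit(parts[1], float(parts[2]))
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparsable row") from exc
    else:
        raise ValueError(f"unknown pfam hit format {format!r}")
    return hits


def write_pfam_hits(hits: dict[str, list[PfamHit]], path: str) -> None:
    rows = [
        {"gene_id": gid, "accession": h.accession, "evalue": h.evalue}
        for gid, gene_hits in hits.items()
        for h in gene_hits
    ]
    pd.DataFrame(rows, columns=["gene_id", "accession", "evalue"]).to_csv(
        path, sep="\t", index=False
    )


def attach_pfam_hits(
    features: Iterable[GeneFeature], hits: dict[str, list[PfamHit]]
) -> None:
    for f in features:
        f.pfam_hits = list(hits.get(f.gene_id, []))


# ---------------------------------------------------------------------------
# DGR component table

DGR_COLUMNS = [
    "contig_id",
    "system_id",
    "rt_gene_id",
    "clade",
    "tr_start",
    "tr_end",
    "vr_intervals",
]


def _encode_vr(vrs: list[tuple[int, int, str]]) -> str:
    return ";".join(f"{s}-{e}:{gid}" for s, e, gid in vrs)


def _decode_vr(text: str) -> list[tuple[int, int, str]]:
    out = []
    for part in str(text).split(";"):
        if not part:
            continue
        span, gid = part.split(":", 1)
        s, e = span.split("-", 1)
        out.append((int(s), int(e), gid))
    return out


def read_dgr_table(path: str) -> list[DgrSystem]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    systems = []
    for row in df.itertuples(index=False):
        clade = int(row.clade) if str(row.clade) not in ("", "nan", "unknown") else CLADE_UNKNOWN
        systems.append(
            DgrSystem(
                contig_id=row.contig_id,
                system_id=row.system_id,
                rt_gene_id=row.rt_gene_id,
                vr_intervals=_decode_vr(row.vr_intervals),
                tr_interval=(int(row.tr_start), int(row.tr_end)),
                clade=clade,
            )
        )
    return systems


def write_dgr_table(systems: Iterable[DgrSystem], path: str) -> None:
    rows = [
        {
            "contig_id": s.contig_id,
            "system_id": s.system_id,
            "rt_gene_id": s.rt_gene_id,
            "clade": s.clade if s.clade != CLADE_UNKNOWN else "unknown",
            "tr_start": s.tr_interval[0],
            "tr_end": s.tr_interval[1],
            "vr_intervals": _encode_vr(s.vr_intervals),
        }
        for s in systems
    ]
    pd.DataFrame(rows, columns=DGR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# immune catalog

def read_immune_catalog(path: str) -> ImmuneCatalog:
    """One Pfam accession per line; ``#`` starts a comment."""
    accessions = []
    with open(path) as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if text:
                accessions.append(text)
    return ImmuneCatalog(accessions)


def write_immune_catalog(catalog: ImmuneCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# immune Pfam catalog (version-stripped accessions)\n")
        for acc in sorted(catalog.accessions):
            fh.write(acc + "\n")


# ---------------------------------------------------------------------------
# generic stage tables

def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a stage-result table as TSV; deterministic column order is the
    caller's DataFrame column order. Floats use repr so tables round-trip."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
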