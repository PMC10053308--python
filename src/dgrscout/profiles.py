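"""Residence, RT-clade, and taxon profiles of candidate systems, plus
gene-map export.

A genuine defense system is expected to be predominantly cellular or
predominantly viral (not evenly split), to carry a single RT clade
(monophyletic origin), and to show taxon-specific clade preferences. These
summaries quantify each of those expectations per composition. Unknown
labels never enter denominators; they are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .composition import Composition
from .dataset import Dataset
from .model import CLADE_UNKNOWN, KNOWN_CLADES

logger = logging.getLogger(__name__)


@dataclass
class ResidenceProfile:
    composition: str
    counts: dict[str, int]  # cellular / viral / unknown
    minority_fraction: float  # min(cellular, viral) / (cellular + viral); NaN if none known


def residence_profile(composition: Composition, dataset: Dataset) -> ResidenceProfile:
    counts = {"cellular": 0, "viral": 0, "unknown": 0}
    for locus in composition.member_loci:
        counts[dataset.contigs[locus.system.contig_id].residence] += 1
    known = counts["cellular"] + counts["viral"]
    minority = (
        min(counts["cellular"], counts["viral"]) / known if known else float("nan")
    )
    return ResidenceProfile(composition.label(), counts, minority)


@dataclass
class CladeProfile:
    composition: str
    counts: dict[int, int]  # clade 1..6 plus CLADE_UNKNOWN
    modal_fraction: float  # over known clades; NaN if none known
    single_clade: bool  # all known-clade members share one clade


def clade_profile(composition: Composition) -> CladeProfile:
    counts = {c: 0 for c in (*KNOWN_CLADES, CLADE_UNKNOWN)}
    for locus in composition.member_loci:
        counts[locus.system.clade] += 1
    known = {c: n for c, n in counts.items() if c != CLADE_UNKNOWN and n > 0}
    total = sum(known.values())
    if total == 0:
        return CladeProfile(composition.label(), counts, float("nan"), False)
    modal = max(known.values()) / total
    return CladeProfile(composition.label(), counts, modal, len(known) == 1)


def taxon_profile(
    compositions: Iterable[Composition], dataset: Dataset
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxon occurrence counts per composition, and the clade-by-taxon
    proportion matrix (rows = taxa, columns = clades 1..6, rows sum to 1
    over known clades)."""
    taxon_rows = []
    clade_taxon: dict[str, dict[int, int]] = {}
    for comp in compositions:
        for locus in comp.member_loci:
            contig = dataset.contigs[locus.system.contig_id]
            taxon_rows.append(
                {"composition": comp.label(), "taxon": contig.taxon}
            )
            if contig.taxon != "unknown" and locus.system.clade != CLADE_UNKNOWN:
                clade_taxon.setdefault(contig.taxon, {c: 0 for c in KNOWN_CLADES})
                clade_taxon[contig.taxon][locus.system.clade] += 1
    if taxon_rows:
        taxon_counts = (
            pd.DataFrame(taxon_rows)
            .value_counts(["composition", "taxon"])
            .rename("count")
            .reset_index()
            .sort_values(["composition", "taxon"], ignore_index=True)
        )
    else:
        taxon_counts = pd.DataFrame(columns=["composition", "taxon", "count"])
    if not clade_taxon:
        logger.warning("no labeled taxa with known clades; clade-by-taxon matrix empty")
        return taxon_counts, pd.DataFrame(
            columns=["taxon"] + [f"clade{c}" for c in KNOWN_CLADES]
        )
    matrix_rows = []
    for taxon in sorted(clade_taxon):
        total = sum(clade_taxon[taxon].values())
        row = {"taxon": taxon}
        for c in KNOWN_CLADES:
            row[f"clade{c}"] = clade_taxon[taxon][c] / total if total else 0.0
        matrix_rows.append(row)
    return taxon_counts, pd.DataFrame(
        matrix_rows, columns=["taxon"] + [f"clade{c}" for c in KNOWN_CLADES]
    )


def profiles_frame(
    compositions: Iterable[Composition], dataset: Dataset
) -> pd.DataFrame:
    rows = []
    for comp in compositions:
        res = residence_profile(comp, dataset)
        cla = clade_profile(comp)
        rows.append(
            {
                "composition": comp.label(),
                "n_loci": comp.n_occurrences,
                "n_cellular": res.counts["cellular"],
                "n_viral": res.counts["viral"],
                "n_residence_unknown": res.counts["unknown"],
                "minority_residence_fraction": res.minority_fraction,
                "modal_clade_fraction": cla.modal_fraction,
                "single_clade": cla.single_clade,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "composition", "n_loci", "n_cellular", "n_viral",
            "n_residence_unknown", "minority_residence_fraction",
            "modal_clade_fraction", "single_clade",
        ],
    )


# ---------------------------------------------------------------------------
# gene-map export (SVG)

_PALETTE = [
    "#4e79a7", "#f28e2b", "#59a14f", "#e15759", "#b07aa1",
    "#76b7b2", "#edc948", "#9c755f", "#bab0ac", "#ff9da7",
]


def _arrow_points(x0: float, x1: float, y: float, h: float, strand: str) -> str:
    head = min(8.0, abs(x1 - x0) / 3.0)
    if strand == "+":
        pts = [
            (x0, y - h / 2), (x1 - head, y - h / 2), (x1, y),
            (x1 - head, y + h / 2), (x0, y + h / 2),
        ]
    else:
        pts = [
            (x1, y - h / 2), (x0 + head, y - h / 2), (x0, y),
            (x0 + head, y + h / 2), (x1, y + h / 2),
        ]
    return " ".join(f"{px:.1f},{py:.1f}" for px, py in pts)


def gene_map_svg(
    composition: Composition,
    dataset: Dataset,
    max_loci: int = 5,
    width: int = 900,
) -> str:
    """Deterministic SVG gene map of up to ``max_loci`` member loci.

    Genes are arrows (left-pointing on the minus strand); the RT gene is
    white, genes of the same Pfam family share a color, and VR-hosting genes
    are labeled "VR".
    """
    rt_ids = {locus.system.rt_gene_id for locus in composition.member_loci}
    color_of: dict[str, str] = {}
    for key in sorted(composition.key):
        if key.accession not in color_of:
            color_of[key.accession] = _PALETTE[len(color_of) % len(_PALETTE)]

    loci = composition.member_loci[:max_loci]
    row_h, gene_h, margin = 46, 16, 20
    height = margin * 2 + row_h * len(loci)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="sans-serif" font-size="10">',
        f'<title>{composition.label()}</title>',
    ]
    for i, locus in enumerate(loci):
        genes = [dataset.gene(g) for g in locus.member_gene_ids]
        if not genes:
            continue
        contig = dataset.contigs[locus.system.contig_id]
        L = contig.length
        origin = genes[0].start
        ends = [((g.start - origin) % L if contig.is_circular else g.start - origin)
                + g.length for g in genes]
        span = max(ends) or 1
        scale = (width - 2 * margin) / span
        y = margin + row_h * i + row_h / 2
        parts.append(
            f'<text x="{margin}" y="{y - gene_h:.1f}">'
            f"{contig.id} / {locus.system.system_id}</text>"
        )
        for g in genes:
            off = (g.start - origin) % L if contig.is_circular else g.start - origin
            x0 = margin + off * scale
            x1 = x0 + g.length * scale
            accs = g.base_accessions()
            if g.gene_id in rt_ids:
                fill = "#ffffff"
            elif accs and accs[0] in color_of:
                fill = color_of[accs[0]]
            else:
                fill = "#d0d0d0"  # irrelevant ORFs in grey
            parts.append(
                f'<polygon points="{_arrow_points(x0, x1, y, gene_h, g.strand)}" '
                f'fill="{fill}" stroke="#333333"/>'
            )
            label = accs[0] if accs else ""
            if g.contains_vr:
                label = (label + " VR").strip()
            if label:
                parts.append(
                    f'<text x="{(x0 + x1) / 2:.1f}" y="{y + gene_h + 9:.1f}" '
                    f'text-anchor="middle">{label}</text>'
                )
    parts.append("</svg>")
    return "\n".join(parts)


def export_gene_maps(
    compositions: Iterable[Composition],
    dataset: Dataset,
    out_dir: str,
    max_loci: int = 5,
) -> list[str]:
    """Write one SVG per composition; returns the written paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, comp in enumerate(
        sorted(compositions, key=lambda c: (-c.n_occurrences, c.label()))
    ):
        path = os.path.join(out_dir, f"composition_{i + 1:02d}.svg")
        with open(path, "w") as fh:
            fh.write(gene_map_svg(comp, dataset, max_loci=max_loci))
        paths.append(path)
    return paths
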