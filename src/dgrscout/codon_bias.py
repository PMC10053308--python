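"""Codon-usage-bias screen for recent horizontal transfer.

A laterally acquired module initially keeps the codon preferences of its
donor, so its genes' codon usage stands out against the rest of the
replicon. The screen compares Wright's effective number of codons (Nc) of
the ORFs inside the putative system region (system span +/- E, default 10
kbp) against ORFs in a control region of identical size placed half the
sequence length away (antipodal under the circularity assumption), using a
two-sample Kolmogorov-Smirnov test per contig. Contigs where the two
regions come closer than ``G_min`` (default 20 kbp) are omitted.

Nc ranges from 20 (one codon per amino acid family: maximal bias) to 61
(uniform synonymous usage). Only ORFs longer than 360 nt enter the
comparison; shorter ones give unstable Nc estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

from .composition import Composition
from .dataset import Dataset
from .intervals import circular_gap, contains_point, linear_gap
from .model import Contig, GeneFeature

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 10_000  # E
DEFAULT_MIN_GAP = 20_000  # G_min
DEFAULT_MIN_ORF = 360  # nt, strict >
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_SAMPLE = 3

NC_FLOOR, NC_CAP = 20.0, 61.0

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: amino acid -> tuple of synonymous codons (standard code, 61 sense codons)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: degeneracy class -> amino acids (singletons Met/Trp enter Nc as the "2")
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _codons in SYNONYMOUS_FAMILIES.items():
    k = len(_codons)
    if k > 1:
        DEGENERACY_CLASSES.setdefault(k, ())
        DEGENERACY_CLASSES[k] += (_aa,)

# class multipliers: number of families per degeneracy class
_CLASS_SIZES = {k: len(aas) for k, aas in DEGENERACY_CLASSES.items()}  # {2:9,3:1,4:5,6:3}


def codon_counts(nt_seq: str) -> dict[str, int]:
    """Count sense codons of an in-frame ORF. Stop codons and codons with
    ambiguous bases are dropped."""
    seq = nt_seq.upper()
    counts: dict[str, int] = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS or any(b not in "ACGT" for b in codon):
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return counts


def _family_homozygosity(counts: dict[str, int], codons: tuple[str, ...]) -> Optional[float]:
    """Wright's F-hat for one synonymous family; None when fewer than two
    codons were observed (the unbiased estimator needs n >= 2)."""
    ns = np.array([counts.get(c, 0) for c in codons], dtype=float)
    n = ns.sum()
    if n < 2:
        return None
    p = ns / n
    return float((n * np.sum(p**2) - 1.0) / (n - 1.0))


def effective_number_of_codons(counts: dict[str, int]) -> float:
    """Wright's Nc from an ORF's codon counts.

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 where Fk is the mean homozygosity
    F-hat over the observed families of degeneracy k. A missing 3-fold class
    (Ile unobserved) is imputed as the mean of F2 and F4 (Wright's fallback);
    any other missing class uses the mean of the available class means. The
    result is capped to [20, 61].
    """
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = [
            f
            for aa in aas
            if (f := _family_homozygosity(counts, SYNONYMOUS_FAMILIES[aa])) is not None
        ]
        if fs:
            class_means[k] = float(np.mean(fs))
    if not class_means:
        raise ValueError("no synonymous family with >= 2 codons observed")
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        class_means[3] = 0.5 * (class_means[2] + class_means[4])
    available = float(np.mean(list(class_means.values())))
    nc = 2.0
    for k in sorted(_CLASS_SIZES):
        f = class_means.get(k, available)
        if f <= 0:
            return NC_CAP  # no detectable bias in some class: treat as unbiased
        nc += _CLASS_SIZES[k] / f
    return float(min(NC_CAP, max(NC_FLOOR, nc)))


# ---------------------------------------------------------------------------
# region pairs

@dataclass
class RegionPair:
    """System region and its equal-length distal control on one contig."""

    contig_id: str
    system_region: tuple[int, int]
    control_region: tuple[int, int]
    gap: int

    @property
    def valid(self) -> bool:
        return True  # invalid pairs are returned as None with a reason


def make_region_pair(
    contig: Contig,
    system_span: tuple[int, int],
    flank_bp: int = DEFAULT_FLANK,
    min_gap_bp: int = DEFAULT_MIN_GAP,
) -> tuple[Optional[RegionPair], str]:
    """Build the (system, control) region pair, or omit with a reason.

    The system region is the system span extended by ``flank_bp`` each side
    (clipped to the contig for linear topology). The control has identical
    length and its midpoint offset by half the contig length — the most
    distant placement under circularity; on linear contigs it is shifted
    back in bounds. Pairs separated by less than ``min_gap_bp`` are omitted.
    """
    L = contig.length
    s, e = system_span
    if contig.is_circular:
        region_len = (e - s) + 2 * flank_bp
        if region_len > L // 2:
            return None, "system region longer than half the contig"
        sys_region = (s - flank_bp, e + flank_bp)
        mid = 0.5 * (sys_region[0] + sys_region[1])
        cmid = mid + L / 2.0
        ctrl = (int(round(cmid - region_len / 2.0)), 0)
        ctrl = (ctrl[0] % L, ctrl[0] % L + region_len)
        sys_region = (sys_region[0] % L, sys_region[0] % L + region_len)
        gap = circular_gap(sys_region, ctrl, L)
    else:
        sys_region = (max(0, s - flank_bp), min(L, e + flank_bp))
        region_len = sys_region[1] - sys_region[0]
        if region_len > L // 2:
            return None, "system region longer than half the contig"
        mid = 0.5 * (sys_region[0] + sys_region[1])
        target = mid + L / 2.0
        c0 = int(round(target - region_len / 2.0))
        c0 = min(max(c0, 0), L - region_len)
        # wrap the target back if it fell beyond the right end entirely
        if c0 == L - region_len and target - region_len / 2.0 > L - region_len:
            pass  # clamped to the far right: farthest in-bounds placement
        ctrl = (c0, c0 + region_len)
        gap = linear_gap(sys_region, ctrl)
    if gap < min_gap_bp:
        return None, f"regions only {gap} bp apart (< {min_gap_bp})"
    return RegionPair(contig.id, sys_region, ctrl, gap), ""


def system_span(dataset: Dataset, system) -> tuple[int, int]:
    """Genomic span covering the DGR core: RT gene, TR, and VR host genes.

    On circular contigs coordinates are unwrapped relative to the RT gene so
    the span stays contiguous across the origin.
    """
    contig = dataset.contigs[system.contig_id]
    L = contig.length
    rt = dataset.gene(system.rt_gene_id)
    anchors: list[tuple[int, int]] = [(rt.start, rt.end), system.tr_interval]
    anchors += [(dataset.gene(g).start, dataset.gene(g).end) for g in system.vr_host_gene_ids()]
    if not contig.is_circular:
        return (min(a for a, _ in anchors), max(b for _, b in anchors))
    ref = rt.start

    def unwrap(iv: tuple[int, int]) -> tuple[int, int]:
        s, b = iv
        d = (s - ref) % L
        if d > L // 2:
            d -= L
        return (ref + d, ref + d + (b - s))

    unwrapped = [unwrap(a) for a in anchors]
    return (min(a for a, _ in unwrapped), max(b for _, b in unwrapped))


# ---------------------------------------------------------------------------
# per-gene Nc and the KS screen

def gene_sequence(gene: GeneFeature, contig: Contig) -> str:
    """Strand-aware coding sequence of a gene (handles origin wrap)."""
    if contig.sequence is None:
        raise ValueError(f"contig {contig.id} has no sequence attached")
    L = contig.length
    if gene.end <= L:
        seq = contig.sequence[gene.start : gene.end]
    else:
        seq = contig.sequence[gene.start :] + contig.sequence[: gene.end - L]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def genes_in_region(
    dataset: Dataset,
    contig: Contig,
    region: tuple[int, int],
    min_orf_nt: int = DEFAULT_MIN_ORF,
) -> list[GeneFeature]:
    """ORFs strictly longer than ``min_orf_nt`` whose midpoint lies in the
    region."""
    return [
        g
        for g in dataset.genes_on(contig.id)
        if g.length > min_orf_nt
        and contains_point(region, g.midpoint(), contig.length, contig.is_circular)
    ]


def nc_for_genes(
    dataset: Dataset, contig: Contig, genes: Iterable[GeneFeature]
) -> list[tuple[str, float]]:
    out = []
    for g in genes:
        try:
            nc = effective_number_of_codons(codon_counts(gene_sequence(g, contig)))
        except ValueError:
            logger.debug("gene %s skipped: no countable synonymous family", g.gene_id)
            continue
        out.append((g.gene_id, nc))
    return out


@dataclass
class KsOutcome:
    contig_id: str
    D: float
    p_value: float
    n_system: int
    n_control: int
    significant: bool
    testable: bool = True
    reason: str = ""


def ks_two_sample(
    x: Iterable[float],
    y: Iterable[float],
    alpha: float = DEFAULT_ALPHA,
    min_sample: int = DEFAULT_MIN_SAMPLE,
    contig_id: str = "",
) -> KsOutcome:
    """Two-sided two-sample Kolmogorov-Smirnov comparison of Nc values,
    asymptotic p-value. Undersized samples yield an untestable outcome."""
    x = list(x)
    y = list(y)
    if len(x) < min_sample or len(y) < min_sample:
        return KsOutcome(
            contig_id, float("nan"), float("nan"), len(x), len(y),
            significant=False, testable=False,
            reason=f"sample sizes {len(x)}/{len(y)} below minimum {min_sample}",
        )
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    p = float(min(1.0, res.pvalue))
    return KsOutcome(
        contig_id, float(res.statistic), p, len(x), len(y),
        significant=p < alpha,
    )


def screen_contig(
    dataset: Dataset,
    system,
    flank_bp: int = DEFAULT_FLANK,
    min_gap_bp: int = DEFAULT_MIN_GAP,
    min_orf_nt: int = DEFAULT_MIN_ORF,
    alpha: float = DEFAULT_ALPHA,
    min_sample: int = DEFAULT_MIN_SAMPLE,
) -> tuple[Optional[KsOutcome], list[tuple[str, str, float]], str]:
    """Run the codon-bias comparison for one DGR system.

    Returns (outcome | None, per-gene Nc rows as (gene_id, region, nc),
    omission reason). ``None`` outcome means the contig was omitted before
    testing (region geometry); untestable outcomes carry ``testable=False``.
    """
    contig = dataset.contigs[system.contig_id]
    span = system_span(dataset, system)
    pair, reason = make_region_pair(contig, span, flank_bp, min_gap_bp)
    if pair is None:
        return None, [], reason
    sys_genes = genes_in_region(dataset, contig, pair.system_region, min_orf_nt)
    ctrl_genes = genes_in_region(dataset, contig, pair.control_region, min_orf_nt)
    sys_nc = nc_for_genes(dataset, contig, sys_genes)
    ctrl_nc = nc_for_genes(dataset, contig, ctrl_genes)
    outcome = ks_two_sample(
        [v for _, v in sys_nc],
        [v for _, v in ctrl_nc],
        alpha=alpha,
        min_sample=min_sample,
        contig_id=contig.id,
    )
    rows = [(g, "system", v) for g, v in sys_nc] + [
        (g, "control", v) for g, v in ctrl_nc
    ]
    return outcome, rows, ""


@dataclass
class BiasScreenResult:
    by_composition: pd.DataFrame  # composition, n_tested, n_significant, proportion
    ks_rows: pd.DataFrame
    nc_rows: pd.DataFrame


def bias_screen(
    dataset: Dataset,
    compositions: Iterable[Composition],
    flank_bp: int = DEFAULT_FLANK,
    min_gap_bp: int = DEFAULT_MIN_GAP,
    min_orf_nt: int = DEFAULT_MIN_ORF,
    alpha: float = DEFAULT_ALPHA,
    min_sample: int = DEFAULT_MIN_SAMPLE,
) -> BiasScreenResult:
    """Per-composition fraction of member contigs with significantly
    different codon usage between system and control regions.

    Omitted (geometry) and untestable (undersized) contigs leave the
    denominator; compositions with no testable contig report NA.
    """
    comp_rows = []
    ks_rows = []
    nc_rows = []
    for comp in compositions:
        n_tested = 0
        n_sig = 0
        for locus in comp.member_loci:
            outcome, gene_rows, reason = screen_contig(
                dataset, locus.system, flank_bp, min_gap_bp, min_orf_nt, alpha, min_sample
            )
            if outcome is None:
                logger.info(
                    "system %s omitted from codon-bias screen: %s",
                    locus.system.system_id, reason,
                )
                continue
            ks_rows.append(
                {
                    "composition": comp.label(),
                    "contig_id": outcome.contig_id,
                    "system_id": locus.system.system_id,
                    "D": outcome.D,
                    "p_value": outcome.p_value,
                    "n_system": outcome.n_system,
                    "n_control": outcome.n_control,
                    "significant": outcome.significant,
                    "testable": outcome.testable,
                }
            )
            for gid, region, nc in gene_rows:
                nc_rows.append(
                    {
                        "contig_id": outcome.contig_id,
                        "system_id": locus.system.system_id,
                        "gene_id": gid,
                        "region": region,
                        "nc": nc,
                    }
                )
            if outcome.testable:
                n_tested += 1
                n_sig += int(outcome.significant)
        comp_rows.append(
            {
                "composition": comp.label(),
                "n_tested": n_tested,
                "n_significant": n_sig,
                "proportion_significant": (n_sig / n_tested) if n_tested else float("nan"),
            }
        )
    return BiasScreenResult(
        by_composition=pd.DataFrame(
            comp_rows,
            columns=["composition", "n_tested", "n_significant", "proportion_significant"],
        ),
        ks_rows=pd.DataFrame(
            ks_rows,
            columns=[
                "composition", "contig_id", "system_id", "D", "p_value",
                "n_system", "n_control", "significant", "testable",
            ],
        ),
        nc_rows=pd.DataFrame(
            nc_rows, columns=["contig_id", "system_id", "gene_id", "region", "nc"]
        ),
    )
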