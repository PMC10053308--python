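"""Synthetic annotated-contig datasets with planted DGR defense loci.

The generator emulates the statistical structure the analysis assumes so
every stage is testable without real metagenome downloads:

* contig lengths log-normal with the mode near 3 kbp, a controllable
  fraction of long (>20 kbp) contigs, linear and circular topology;
* one planted DGR cassette per contig: an RT gene, a TR, and a VR inside a
  target gene, plus an Avd-like accessory gene;
* an immune-Pfam gene placed within the cassette (hence within 10 kbp of
  RT/VR) with probability ``p_immune_colocalization`` and uniformly outside
  the bait windows otherwise;
* background decoy genes with Pfams drawn from a decoy pool, placed with no
  positional association to the DGR;
* the cassette keeps its canonical gene order/orientation with probability
  ``arrangement_conservation`` and is scrambled uniformly otherwise;
* gene nucleotide sequences sampled codon-by-codon from a background codon
  usage table, except genes inside the planted island, which use a table
  skewed by ``codon_shift_delta`` (0 = identical to background, 1 = one
  codon per family);
* residence/clade/taxon labels with a configurable viral fraction and a
  taxon-conditional clade bias.

VR realism is qualitative only: the VR is a TR copy with substitutions at
adenine positions; no retrohoming dynamics are simulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import io as dio
from .dataset import Dataset
from .model import Contig, DgrSystem, GeneFeature, ImmuneCatalog, PfamHit

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# planted Pfam accessions
PFAM_RT = "PF00078"      # reverse transcriptase
PFAM_AVD = "PF05635"     # Avd-like accessory
PFAM_TARGET = "PF01833"  # VR-hosting target gene
PFAM_IMMUNE = "PF01797"  # planted immune family

#: catalog used by default in simulations; includes families never planted
DEFAULT_IMMUNE_ACCESSIONS = (PFAM_IMMUNE, "PF13455", "PF18742")

CANONICAL_ROLES = ("immune", "avd", "rt", "target")


def _build_usage(delta: float = 0.0) -> dict[str, dict[str, float]]:
    """Per-amino-acid synonymous codon probabilities.

    The background table (delta=0) weights the codons of each family
    1, 1/2, 1/3, ... (moderate, realistic bias). ``delta`` interpolates
    toward a degenerate table concentrated on each family's *least* used
    background codon, so islands shift away from the background preference.
    """
    from .codon_bias import SYNONYMOUS_FAMILIES

    table: dict[str, dict[str, float]] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        codons = tuple(sorted(codons))
        w = np.array([1.0 / (i + 1) for i in range(len(codons))])
        p = w / w.sum()
        if delta > 0 and len(codons) > 1:
            onehot = np.zeros(len(codons))
            onehot[-1] = 1.0  # least-used background codon becomes preferred
            p = (1.0 - delta) * p + delta * onehot
        table[aa] = {c: float(x) for c, x in zip(codons, p / p.sum())}
    return table


def sample_codons(aa_sequence: str, usage_table: dict[str, dict[str, float]],
                  rng: np.random.Generator) -> str:
    """Sample a coding nucleotide sequence for a protein.

    The translation of the result equals ``aa_sequence``; codon frequencies
    converge to ``usage_table`` as the protein length grows. Sampling is
    vectorized per amino acid (inverse-CDF on one uniform draw per residue).
    """
    missing = set(aa_sequence) - set(usage_table)
    if missing:
        raise ValueError(f"amino acid(s) absent from usage table: {sorted(missing)}")
    n = len(aa_sequence)
    if n == 0:
        return ""
    u = rng.random(n)
    aa_arr = np.frombuffer(aa_sequence.encode(), dtype="S1")
    out = np.empty(n, dtype="S3")
    for aa in sorted(set(aa_sequence)):
        fam = usage_table[aa]
        codons = np.array(list(fam), dtype="S3")
        probs = np.fromiter(fam.values(), dtype=float)
        cdf = np.cumsum(probs / probs.sum())
        pos = np.nonzero(aa_arr == aa.encode())[0]
        idx = np.minimum(np.searchsorted(cdf, u[pos], side="right"), len(codons) - 1)
        out[pos] = codons[idx]
    return out.tobytes().decode()


def _sample_gene_nt(n_codons: int, usage: dict[str, dict[str, float]],
                    rng: np.random.Generator) -> str:
    """Random gene: ATG + sampled codons for a random protein + TAA stop."""
    body_len = n_codons - 2
    aas = "".join(AA20[i] for i in rng.integers(0, len(AA20), size=body_len))
    return "ATG" + sample_codons(aas, usage, rng) + "TAA"


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Lengths are bp; probabilities in [0, 1]. Defaults describe a realistic
    metagenomic collection: length mode 3 kbp with half the contigs longer
    than 20 kbp, a 25% viral minority, near-perfect (98%) cassette order
    conservation, and a moderate decoy gene background.
    """

    n_contigs: int = 100
    seed: int = 0
    # contig lengths: log-normal with given mode, truncated to [min, max]
    length_mode_bp: int = 3_000
    length_sigma: float = 1.2
    min_length_bp: int = 3_000
    max_length_bp: int = 200_000
    fraction_long: float = 0.5          # P(length > 20 kbp)
    long_threshold_bp: int = 20_000
    p_circular: float = 0.5
    # cassette / immune placement
    p_immune_colocalization: float = 0.9
    colocalization_window_bp: int = 10_000
    arrangement_conservation: float = 0.98
    # background decoys
    background_pfam_rate: float = 0.3   # decoy genes per kbp
    n_decoy_pfams: int = 30
    decoy_len_range: tuple[int, int] = (300, 2_400)
    # codon usage island
    codon_shift_delta: float = 0.0
    island_flank_bp: int = 10_000
    with_sequences: bool = True
    # labels
    p_viral: float = 0.25
    clade_weights: tuple[float, ...] = (1 / 6,) * 6
    taxa: tuple[str, ...] = (
        "Pseudomonadota", "Bacteroidota", "Bacillota", "Actinomycetota", "Cyanobacteriota",
    )
    taxon_clade_bias: float = 0.8       # P(clade drawn from the taxon's preferred pair)

    def __post_init__(self) -> None:
        for name in ("fraction_long", "p_circular", "p_immune_colocalization",
                     "arrangement_conservation", "codon_shift_delta", "p_viral",
                     "taxon_clade_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.clade_weights) - 1.0) > 1e-9 or len(self.clade_weights) != 6:
            raise ValueError("clade_weights must be a 6-vector summing to 1")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")


@dataclass
class SimulatedDataset:
    """A generated dataset plus its ground truth."""

    config: SimConfig
    dataset: Dataset
    immune_catalog: ImmuneCatalog
    ground_truth: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str) -> dict[str, str]:
        """Emit the exact input formats of the analysis plus ground truth."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "contigs": os.path.join(out_dir, "contigs.tsv"),
            "gff3": os.path.join(out_dir, "features.gff3"),
            "pfam": os.path.join(out_dir, "pfam_hits.tsv"),
            "dgr": os.path.join(out_dir, "dgr_systems.tsv"),
            "immune": os.path.join(out_dir, "immune_pfams.txt"),
            "ground_truth": os.path.join(out_dir, "ground_truth.tsv"),
        }
        dio.write_contig_table(self.dataset.contigs.values(), paths["contigs"])
        dio.write_gff3(self.dataset.features, paths["gff3"])
        hits = {f.gene_id: f.pfam_hits for f in self.dataset.features if f.pfam_hits}
        dio.write_pfam_hits(hits, paths["pfam"])
        dio.write_dgr_table(self.dataset.systems, paths["dgr"])
        dio.write_immune_catalog(self.immune_catalog, paths["immune"])
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
        if self.sequences:
            paths["fasta"] = os.path.join(out_dir, "contigs.fasta")
            dio.write_fasta(self.sequences, paths["fasta"])
        return paths


@dataclass
class _GenePlan:
    gene_id: str
    start: int
    end: int
    strand: str
    pfam: Optional[str]
    role: str  # immune / avd / rt / target / decoy


def _draw_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    mu = math.log(cfg.length_mode_bp) + cfg.length_sigma**2
    want_long = rng.random() < cfg.fraction_long
    for _ in range(10_000):
        L = int(rng.lognormal(mu, cfg.length_sigma))
        if not (cfg.min_length_bp <= L <= cfg.max_length_bp):
            continue
        if (L > cfg.long_threshold_bp) == want_long:
            return L
    raise RuntimeError("length distribution incompatible with fraction_long")


def _preferred_clades(taxon_idx: int) -> tuple[int, int]:
    """Fixed taxon -> (primary, secondary) clade mapping."""
    primary = (2 * taxon_idx) % 6 + 1
    secondary = (2 * taxon_idx + 1) % 6 + 1
    return primary, secondary


def _cassette_lengths(rng: np.random.Generator) -> dict[str, int]:
    def mult3(lo: int, hi: int) -> int:
        return 3 * int(rng.integers(lo // 3, hi // 3 + 1))

    return {
        "immune": mult3(600, 900),
        "avd": mult3(360, 480),
        "rt": mult3(900, 1200),
        "target": mult3(600, 1200),
    }


def _plan_cassette(
    cfg: SimConfig, rng: np.random.Generator, with_immune: bool
) -> tuple[list[tuple[str, int, str]], bool]:
    """Choose cassette gene order/strands and lengths.

    Returns ([(role, length, strand), ...] left to right, conserved_flag).
    """
    lens = _cassette_lengths(rng)
    roles = [r for r in CANONICAL_ROLES if with_immune or r != "immune"]
    conserved = rng.random() < cfg.arrangement_conservation
    if conserved:
        order = roles
        strands = ["+"] * len(roles)
    else:
        order = [roles[i] for i in rng.permutation(len(roles))]
        strands = ["+" if rng.random() < 0.5 else "-" for _ in roles]
    return [(r, lens[r], s) for r, s in zip(order, strands)], conserved


def _place_uniform_outside(
    L: int, gene_len: int, forbidden: list[tuple[int, int]],
    occupied: list[tuple[int, int]], rng: np.random.Generator,
) -> Optional[int]:
    """Uniform random start such that the gene avoids forbidden windows and
    occupied spans; None if no placement found."""
    for _ in range(200):
        start = int(rng.integers(0, max(1, L - gene_len)))
        iv = (start, start + gene_len)
        if any(iv[0] < f[1] and f[0] < iv[1] for f in forbidden):
            continue
        if any(iv[0] < o[1] and o[0] < iv[1] for o in occupied):
            continue
        return start
    return None


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one dataset; byte-identical for a fixed config and seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bg_usage = _build_usage(0.0)
    island_usage = _build_usage(cfg.codon_shift_delta)
    decoy_pool = [f"PF9{i:04d}" for i in range(cfg.n_decoy_pfams)]

    contigs: dict[str, Contig] = {}
    features: list[GeneFeature] = []
    systems: list[DgrSystem] = []
    sequences: dict[str, str] = {}
    truth_rows: list[dict] = []
    n_resampled = 0

    for ci in range(cfg.n_contigs):
        cid = f"contig{ci + 1:05d}"
        # --- cassette plan (gene order, lengths, strands) ---
        coloc = rng.random() < cfg.p_immune_colocalization
        plan, conserved = _plan_cassette(cfg, rng, with_immune=coloc)
        gaps = [int(rng.integers(50, 151)) for _ in plan]
        tr_len = 100
        tr_gap = int(rng.integers(20, 61))
        cassette_span = sum(l for _, l, _ in plan) + sum(gaps) + tr_len + tr_gap

        # --- contig length (resampled until the cassette fits) ---
        L = _draw_length(cfg, rng)
        while L < cassette_span + 200:
            n_resampled += 1
            L = _draw_length(cfg, rng)

        topology = "circular" if rng.random() < cfg.p_circular else "linear"
        residence = "viral" if rng.random() < cfg.p_viral else "cellular"
        taxon_idx = int(rng.integers(0, len(cfg.taxa)))
        taxon = cfg.taxa[taxon_idx]
        if rng.random() < cfg.taxon_clade_bias:
            pref = _preferred_clades(taxon_idx)
            clade = int(pref[0] if rng.random() < 0.75 else pref[1])
        else:
            clade = 1 + int(rng.choice(6, p=np.asarray(cfg.clade_weights)))

        # --- lay out the cassette ---
        cassette_start = int(rng.integers(0, L - cassette_span - 100))
        pos = cassette_start
        genes: list[_GenePlan] = []
        tr_interval: Optional[tuple[int, int]] = None
        role_pfam = {
            "immune": PFAM_IMMUNE, "avd": PFAM_AVD, "rt": PFAM_RT, "target": PFAM_TARGET,
        }
        for k, ((role, glen, strand), gap) in enumerate(zip(plan, gaps)):
            gid = f"{cid}_g{len(genes) + 1:03d}"
            genes.append(_GenePlan(gid, pos, pos + glen, strand, role_pfam[role], role))
            pos += glen
            if role == "rt":
                tr_interval = (pos + tr_gap, pos + tr_gap + tr_len)
                pos += tr_gap + tr_len
            pos += gap
        cassette_interval = (cassette_start, pos)
        assert tr_interval is not None

        rt_gene = next(g for g in genes if g.role == "rt")
        target_gene = next(g for g in genes if g.role == "target")
        # VR inside the target gene, codon-aligned, away from start/stop
        vr_len = tr_len
        max_off = target_gene.end - target_gene.start - vr_len - 6
        vr_off = 3 + 3 * int(rng.integers(0, max(1, (max_off - 3) // 3)))
        vr_interval = (target_gene.start + vr_off, target_gene.start + vr_off + vr_len)

        # --- immune gene away from the baits when not co-localized ---
        immune_planted = coloc
        W = cfg.colocalization_window_bp
        if not coloc:
            glen = _cassette_lengths(rng)["immune"]
            forbidden = [
                (rt_gene.start - W - glen, rt_gene.end + W),
                (target_gene.start - W - glen, target_gene.end + W),
            ]
            forbidden = [(max(0, a), min(L, b)) for a, b in forbidden]
            occupied = [cassette_interval]
            start = _place_uniform_outside(L, glen, forbidden, occupied, rng)
            if start is not None:
                gid = f"{cid}_g{len(genes) + 1:03d}"
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(_GenePlan(gid, start, start + glen, strand, PFAM_IMMUNE, "immune"))
                immune_planted = True
            else:
                logger.debug("contig %s: no room for a distal immune gene; omitted", cid)

        # --- background decoys ---
        n_decoys = int(rng.poisson(cfg.background_pfam_rate * L / 1000.0))
        occupied = [(g.start, g.end) for g in genes] + [tr_interval]
        lo, hi = cfg.decoy_len_range
        for _ in range(n_decoys):
            glen = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
            start = _place_uniform_outside(L, glen, [], occupied, rng)
            if start is None:
                continue
            gid = f"{cid}_g{len(genes) + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            pfam = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
            genes.append(_GenePlan(gid, start, start + glen, strand, pfam, "decoy"))
            occupied.append((start, start + glen))

        genes.sort(key=lambda g: g.start)

        # --- island: codon-shifted region around the cassette ---
        island = (
            max(0, cassette_interval[0] - cfg.island_flank_bp),
            min(L, cassette_interval[1] + cfg.island_flank_bp),
        )

        # --- emit domain objects ---
        contigs[cid] = Contig(cid, L, topology=topology, residence=residence, taxon=taxon)
        for g in genes:
            evalue = float(10.0 ** -rng.uniform(5, 30))
            features.append(
                GeneFeature(
                    gene_id=g.gene_id, contig_id=cid, start=g.start, end=g.end,
                    strand=g.strand,
                    pfam_hits=[PfamHit(g.pfam, evalue)] if g.pfam else [],
                )
            )
        systems.append(
            DgrSystem(
                contig_id=cid,
                system_id=f"dgr_{cid}",
                rt_gene_id=rt_gene.gene_id,
                vr_intervals=[(vr_interval[0], vr_interval[1], target_gene.gene_id)],
                tr_interval=tr_interval,
                clade=clade,
            )
        )

        # --- nucleotide sequence ---
        if cfg.with_sequences:
            arr = np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=L)].copy()
            for g in genes:
                in_island = g.start >= island[0] and g.end <= island[1]
                usage = island_usage if in_island else bg_usage
                nt = _sample_gene_nt((g.end - g.start) // 3, usage, rng)
                if g.strand == "-":
                    from Bio.Seq import Seq

                    nt = str(Seq(nt).reverse_complement())
                arr[g.start : g.end] = np.frombuffer(nt.encode(), dtype="S1")
            # TR, and VR as a TR copy mutated at adenine positions
            tr_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=tr_len))
            vr_seq = "".join(
                ("ACGT"[int(rng.integers(0, 4))] if b == "A" else b) for b in tr_seq
            )
            arr[tr_interval[0] : tr_interval[1]] = np.frombuffer(tr_seq.encode(), dtype="S1")
            arr[vr_interval[0] : vr_interval[1]] = np.frombuffer(vr_seq.encode(), dtype="S1")
            sequences[cid] = arr.tobytes().decode()
            contigs[cid].sequence = sequences[cid]

        planted_key = sorted(
            {("VR." if g.role == "target" else "") + g.pfam
             for g in genes if g.role != "decoy"}
        )
        cass_sig = ",".join(
            f"{g.pfam}{g.strand}" for g in genes
            if g.role != "decoy" and cassette_interval[0] <= g.start < cassette_interval[1]
        )
        truth_rows.append(
            {
                "contig_id": cid,
                "length": L,
                "topology": topology,
                "planted_composition": "+".join(planted_key),
                "planted_pfams": ",".join(sorted({g.pfam for g in genes if g.role != "decoy"})),
                "arrangement_signature": cass_sig,
                "arrangement_conserved": conserved,
                "immune_planted": immune_planted,
                "immune_colocalized": coloc,
                "island_start": island[0],
                "island_end": island[1],
                "cassette_start": cassette_interval[0],
                "cassette_end": cassette_interval[1],
                "residence": residence,
                "clade": clade,
                "taxon": taxon,
            }
        )

    if n_resampled:
        logger.warning(
            "resampled %d contig lengths too short for their cassette", n_resampled
        )

    dataset = Dataset.assemble(contigs, features, systems)
    return SimulatedDataset(
        config=cfg,
        dataset=dataset,
        immune_catalog=ImmuneCatalog(DEFAULT_IMMUNE_ACCESSIONS),
        ground_truth=pd.DataFrame(truth_rows),
        sequences=sequences,
    )


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("clade_weights", "taxa", "decoy_len_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimConfig(**d)


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for key in ("clade_weights", "taxa", "decoy_len_range"):
        d[key] = list(d[key])
    return d
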