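"""Icity: redundancy-weighted gene-neighborhood co-localization scoring.

The Icity score of a protein cluster is ``w'/w``: the weighted fraction of
the cluster's members that fall within a fixed window (default 10 kbp) of a
bait gene class. Baits are the two DGR components most diagnostic of a
functional locus — the reverse transcriptase (RT) gene and each VR-hosting
target gene. Scores near 1 indicate that essentially every occurrence of a
family in the dataset sits next to a DGR, i.e. a probable functional
association.

Clusters are version-stripped Pfam families; proteins that host a variable
repeat form a separate cluster from their non-VR peers of the same family
(``ClusterKey.vr_flag``).

Redundancy weighting guards against datasets dominated by near-identical
loci: neighborhoods with an identical Pfam-content fingerprint are treated
as one observation, and each member gene carries weight ``1/k`` where ``k``
neighborhoods share its home fingerprint.

The multi-run protocol re-scores seeded random subsamples of the contigs
until two consecutive runs reveal no new cluster above the score threshold,
then reports per-cluster means over all runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .dataset import Dataset
from .intervals import overlaps
from .model import GeneFeature

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000
DEFAULT_THRESHOLD = 0.7
DEFAULT_SUBSAMPLE = 0.8
MAX_RUNS = 25


class ClusterKey(NamedTuple):
    """Identity of a protein cluster: Pfam family x VR status."""

    accession: str  # version-stripped, e.g. "PF05635"
    vr_flag: bool

    def label(self) -> str:
        return ("VR." if self.vr_flag else "") + self.accession


def cluster_keys_of(gene: GeneFeature) -> list[ClusterKey]:
    return [ClusterKey(acc, gene.contains_vr) for acc in gene.base_accessions()]


@dataclass
class Neighborhood:
    """Window of +/- D bp around one bait gene, with its member genes."""

    bait_kind: str  # "RT" or "VR"
    bait_gene_id: str
    contig_id: str
    window: tuple[int, int]
    member_gene_ids: list[str]

    def fingerprint(self, dataset: Dataset) -> tuple:
        """Ordered cluster content of the neighborhood, used to spot
        redundant (duplicated) loci."""
        return tuple(
            tuple(sorted(cluster_keys_of(dataset.gene(g))))
            for g in self.member_gene_ids
        )


def extract_neighborhoods(
    dataset: Dataset,
    window_bp: int = DEFAULT_WINDOW,
    bait_kinds: tuple[str, ...] = ("RT", "VR"),
) -> list[Neighborhood]:
    """One neighborhood per bait gene (RT gene; each VR host gene).

    A gene is a member iff its interval overlaps the bait window by >= 1 bp;
    on circular contigs the window wraps the origin. The bait gene is always
    a member of its own neighborhood.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    baits: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for s in dataset.systems:
        candidates = []
        if "RT" in bait_kinds:
            candidates.append(("RT", s.rt_gene_id))
        if "VR" in bait_kinds:
            candidates.extend(("VR", g) for g in s.vr_host_gene_ids())
        for kind, gid in candidates:
            if (kind, gid) not in seen:
                seen.add((kind, gid))
                baits.append((kind, gid))

    out: list[Neighborhood] = []
    for kind, gid in baits:
        bait = dataset.gene(gid)
        contig = dataset.contigs[bait.contig_id]
        L = contig.length
        if contig.is_circular:
            win = (bait.start - window_bp, bait.end + window_bp)
            if win[1] - win[0] >= L:
                win = (0, L)
        else:
            win = (max(0, bait.start - window_bp), min(L, bait.end + window_bp))
        members = [
            f.gene_id
            for f in dataset.genes_on(bait.contig_id)
            if overlaps((f.start, f.end), win, L, contig.is_circular)
        ]
        out.append(
            Neighborhood(
                bait_kind=kind,
                bait_gene_id=gid,
                contig_id=bait.contig_id,
                window=win,
                member_gene_ids=members,
            )
        )
    return out


def redundancy_weights(
    neighborhoods: list[Neighborhood], dataset: Dataset
) -> dict[str, float]:
    """Down-weight genes from duplicated loci.

    Neighborhoods are grouped by identical content fingerprint; each member
    gene gets weight ``1/k`` where ``k`` neighborhoods share the fingerprint
    of the gene's home neighborhood (its first containing neighborhood in a
    deterministic order). Genes outside every neighborhood keep weight 1.
    """
    fingerprints = [nb.fingerprint(dataset) for nb in neighborhoods]
    counts: dict[tuple, int] = {}
    for fp in fingerprints:
        counts[fp] = counts.get(fp, 0) + 1

    order = sorted(
        range(len(neighborhoods)),
        key=lambda i: (
            neighborhoods[i].contig_id,
            neighborhoods[i].bait_gene_id,
            neighborhoods[i].bait_kind,
        ),
    )
    weights: dict[str, float] = {f.gene_id: 1.0 for f in dataset.features}
    assigned: set[str] = set()
    for i in order:
        k = counts[fingerprints[i]]
        for gid in neighborhoods[i].member_gene_ids:
            if gid not in assigned:
                assigned.add(gid)
                weights[gid] = 1.0 / k
    return weights


def icity_score(
    cluster: ClusterKey,
    weights: dict[str, float],
    neighborhoods: list[Neighborhood],
    dataset: Dataset,
) -> float:
    """w'/w for one cluster: weighted fraction of its members co-localized
    with at least one bait neighborhood."""
    members = [f for f in dataset.features if cluster in cluster_keys_of(f)]
    if not members:
        raise ValueError(f"cluster {cluster} has no members in the dataset")
    in_any: set[str] = set()
    for nb in neighborhoods:
        in_any.update(nb.member_gene_ids)
    w = sum(weights[f.gene_id] for f in members)
    w_prime = sum(weights[f.gene_id] for f in members if f.gene_id in in_any)
    return w_prime / w


def score_all_clusters(
    dataset: Dataset,
    window_bp: int = DEFAULT_WINDOW,
    bait_kinds: tuple[str, ...] = ("RT", "VR"),
) -> dict[ClusterKey, float]:
    """Score every cluster in the dataset against one bait class."""
    neighborhoods = extract_neighborhoods(dataset, window_bp, bait_kinds)
    weights = redundancy_weights(neighborhoods, dataset)
    in_any: set[str] = set()
    for nb in neighborhoods:
        in_any.update(nb.member_gene_ids)
    w: dict[ClusterKey, float] = {}
    w_prime: dict[ClusterKey, float] = {}
    for f in dataset.features:
        for key in cluster_keys_of(f):
            w[key] = w.get(key, 0.0) + weights[f.gene_id]
            if f.gene_id in in_any:
                w_prime[key] = w_prime.get(key, 0.0) + weights[f.gene_id]
    return {key: w_prime.get(key, 0.0) / w[key] for key in w}


@dataclass
class IcityTable:
    """Per-cluster scores across runs of the subsampled protocol."""

    run_scores: dict[ClusterKey, list[float]]
    n_runs: int
    run_seeds: list[int]
    # weighted member counts from a full-dataset pass (max-scoring bait side)
    w: dict[ClusterKey, float] = field(default_factory=dict)
    w_prime: dict[ClusterKey, float] = field(default_factory=dict)

    def mean_scores(self) -> dict[ClusterKey, float]:
        return {
            key: float(np.mean(scores))
            for key, scores in self.run_scores.items()
            if scores
        }

    def clusters(self) -> list[ClusterKey]:
        return sorted(self.run_scores)

    def to_frame(self):
        import pandas as pd

        means = self.mean_scores()
        rows = []
        for key in self.clusters():
            scores = self.run_scores[key]
            row = {
                "pfam": key.accession,
                "vr_flag": key.vr_flag,
            }
            for i in range(self.n_runs):
                row[f"run{i + 1}"] = scores[i] if i < len(scores) else np.nan
            row["mean"] = means.get(key, np.nan)
            row["w"] = self.w.get(key, np.nan)
            row["w_prime"] = self.w_prime.get(key, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df) -> "IcityTable":
        run_cols = sorted(
            (c for c in df.columns if c.startswith("run")),
            key=lambda c: int(c[3:]),
        )
        run_scores: dict[ClusterKey, list[float]] = {}
        w: dict[ClusterKey, float] = {}
        w_prime: dict[ClusterKey, float] = {}
        for row in df.itertuples(index=False):
            key = ClusterKey(row.pfam, bool(row.vr_flag))
            scores = [getattr(row, c) for c in run_cols]
            run_scores[key] = [float(s) for s in scores if not np.isnan(s)]
            w[key] = float(row.w)
            w_prime[key] = float(row.w_prime)
        return cls(
            run_scores=run_scores,
            n_runs=len(run_cols),
            run_seeds=[],
            w=w,
            w_prime=w_prime,
        )


def run_icity(
    dataset: Dataset,
    window_bp: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    subsample_fraction: float = DEFAULT_SUBSAMPLE,
    seed: int = 0,
    n_min_runs: int = 2,
    max_runs: int = MAX_RUNS,
) -> IcityTable:
    """Multi-run Icity protocol with seeded contig subsampling.

    Each run draws ``subsample_fraction`` of the contigs without replacement,
    scores every cluster against RT baits and against VR baits separately,
    and records the maximum of the two. Runs continue until a run (after the
    minimum of ``n_min_runs``) reveals no new cluster exceeding ``threshold``
    relative to all earlier runs, so the last two consecutive runs agree on
    the above-threshold set. With ``subsample_fraction=1`` every run is
    identical and the protocol stops after exactly ``n_min_runs`` runs.
    """
    if not dataset.systems:
        raise ValueError("dataset has no DGR systems")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")

    contig_ids = sorted(dataset.contigs)
    dgr_contigs = {s.contig_id for s in dataset.systems}
    n_take = max(1, int(round(subsample_fraction * len(contig_ids))))
    ss = np.random.SeedSequence(seed)
    run_seeds_all = [int(s) for s in ss.generate_state(max_runs)]

    run_scores: dict[ClusterKey, list[float]] = {}
    seen_above: set[ClusterKey] = set()
    used_seeds: list[int] = []
    n_runs = 0
    for run_idx in range(max_runs):
        rng = np.random.default_rng(run_seeds_all[run_idx])
        if subsample_fraction >= 1.0:
            chosen = contig_ids
        else:
            for _ in range(100):
                chosen = sorted(
                    rng.choice(contig_ids, size=n_take, replace=False).tolist()
                )
                if any(c in dgr_contigs for c in chosen):
                    break
                warnings.warn("subsample contained no DGR contig; resampling")
            else:  # pragma: no cover - pathological configuration
                raise RuntimeError("could not draw a subsample with a DGR contig")
        sub = dataset.subset(chosen)
        scores_rt = score_all_clusters(sub, window_bp, bait_kinds=("RT",))
        scores_vr = score_all_clusters(sub, window_bp, bait_kinds=("VR",))
        this_run: dict[ClusterKey, float] = {}
        for key in set(scores_rt) | set(scores_vr):
            this_run[key] = max(scores_rt.get(key, 0.0), scores_vr.get(key, 0.0))
        for key, score in this_run.items():
            run_scores.setdefault(key, []).append(score)
        used_seeds.append(run_seeds_all[run_idx])
        n_runs += 1

        new_above = {k for k, v in this_run.items() if v > threshold} - seen_above
        seen_above |= new_above
        if n_runs >= n_min_runs and not new_above:
            break
    else:  # pragma: no cover - cap is generous
        logger.warning("icity protocol hit the %d-run cap without converging", max_runs)

    logger.info("icity converged after %d runs (%d clusters)", n_runs, len(run_scores))

    # full-dataset pass for reported weighted counts
    table = IcityTable(run_scores=run_scores, n_runs=n_runs, run_seeds=used_seeds)
    for kinds in (("RT",), ("VR",)):
        nbs = extract_neighborhoods(dataset, window_bp, kinds)
        weights = redundancy_weights(nbs, dataset)
        in_any: set[str] = set()
        for nb in nbs:
            in_any.update(nb.member_gene_ids)
        w: dict[ClusterKey, float] = {}
        wp: dict[ClusterKey, float] = {}
        for f in dataset.features:
            for key in cluster_keys_of(f):
                w[key] = w.get(key, 0.0) + weights[f.gene_id]
                if f.gene_id in in_any:
                    wp[key] = wp.get(key, 0.0) + weights[f.gene_id]
        for key in w:
            score = wp.get(key, 0.0) / w[key]
            prev = (
                table.w_prime.get(key, 0.0) / table.w[key]
                if key in table.w
                else -1.0
            )
            if score > prev:
                table.w[key] = w[key]
                table.w_prime[key] = wp.get(key, 0.0)
    return table


def select_pfams(
    table: IcityTable,
    mode: str = "all_runs",
    threshold: float = DEFAULT_THRESHOLD,
) -> set[ClusterKey]:
    """Select clusters by score threshold (strict inequality).

    ``all_runs`` (strict) keeps a cluster only if every recorded run score
    exceeds the threshold; ``any_run`` (lenient) if at least one does. The
    strict set is always a subset of the lenient one.
    """
    if mode not in ("all_runs", "any_run"):
        raise ValueError(f"unknown selection mode {mode!r}")
    selected: set[ClusterKey] = set()
    for key, scores in table.run_scores.items():
        if not scores:
            continue
        if mode == "all_runs" and all(s > threshold for s in scores):
            selected.add(key)
        elif mode == "any_run" and any(s > threshold for s in scores):
            selected.add(key)
    return selected
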