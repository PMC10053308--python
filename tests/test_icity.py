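"""Neighborhood extraction, redundancy weighting, and w'/w scoring,
cross-checked against brute-force oracles on small fixtures."""

import numpy as np
import pytest

from dgrscout.dataset import Dataset
from dgrscout.icity import (
    ClusterKey,
    cluster_keys_of,
    extract_neighborhoods,
    icity_score,
    redundancy_weights,
    run_icity,
    select_pfams,
)
from dgrscout.model import Contig, DgrSystem

from conftest import make_gene


def dataset_of(contigs, features, systems):
    return Dataset.assemble(contigs, features, systems)


class TestNeighborhoodBoundaries:
    def _ds(self, extra_genes, L=40_000, topology="linear"):
        contigs = {"c": Contig("c", L, topology=topology)}
        features = [make_gene("rt", "c", 5_000, 6_000, "+", ["PF00078"])] + extra_genes
        systems = [
            DgrSystem("c", "s", "rt", [(5_100, 5_200, "rt")], (6_100, 6_200))
        ]
        return dataset_of(contigs, features, systems)

    def test_one_bp_overlap_with_window_end_is_membership(self):
        # window end = 6000 + 10000 = 16000; gene [15999,17000) overlaps by 1 bp
        ds = self._ds([make_gene("g", "c", 15_999, 17_000, "+", ["PF00001"])])
        nb = next(n for n in extract_neighborhoods(ds, 10_000) if n.bait_kind == "RT")
        assert "g" in nb.member_gene_ids

    def test_half_open_boundary_excludes_gene_at_window_end(self):
        ds = self._ds([make_gene("g", "c", 16_000, 17_000, "+", ["PF00001"])])
        nb = next(n for n in extract_neighborhoods(ds, 10_000) if n.bait_kind == "RT")
        assert "g" not in nb.member_gene_ids

    def test_window_wraps_on_circular_contig(self):
        contigs = {"c": Contig("c", 20_000, topology="circular")}
        features = [
            make_gene("rt", "c", 19_000, 20_000, "+", ["PF00078"]),
            make_gene("g", "c", 0, 500, "+", ["PF00001"]),
        ]
        systems = [DgrSystem("c", "s", "rt", [(19_100, 19_200, "rt")], (19_300, 19_400))]
        ds = dataset_of(contigs, features, systems)
        nb = next(n for n in extract_neighborhoods(ds, 10_000) if n.bait_kind == "RT")
        assert "g" in nb.member_gene_ids

    def test_bait_gene_is_member_of_its_own_neighborhood(self):
        ds = self._ds([])
        for nb in extract_neighborhoods(ds, 10_000):
            assert nb.bait_gene_id in nb.member_gene_ids


def replicated_loci_dataset(n_shared, n_unique, spacing=50_000):
    """One long contig per locus; ``n_shared`` identical loci and
    ``n_unique`` loci with distinct Pfam content."""
    contigs, features, systems = {}, [], []
    for i in range(n_shared + n_unique):
        cid = f"c{i}"
        contigs[cid] = Contig(cid, spacing)
        acc = "PF00011" if i < n_shared else f"PF001{20 + i:02d}"
        features += [
            make_gene(f"rt{i}", cid, 5_000, 6_000, "+", ["PF00078"]),
            make_gene(f"x{i}", cid, 7_000, 8_000, "+", [acc]),
        ]
        systems.append(
            DgrSystem(cid, f"s{i}", f"rt{i}", [(5_100, 5_200, f"rt{i}")], (6_100, 6_200))
        )
    return dataset_of(contigs, features, systems)


class TestRedundancyWeights:
    def test_identical_fingerprints_share_weight(self):
        ds = replicated_loci_dataset(4, 0)
        nbs = extract_neighborhoods(ds, 10_000, bait_kinds=("RT",))
        w = redundancy_weights(nbs, ds)
        for nb in nbs:
            for gid in nb.member_gene_ids:
                assert w[gid] == pytest.approx(0.25)

    def test_unique_fingerprints_keep_weight_one(self):
        ds = replicated_loci_dataset(0, 4)
        nbs = extract_neighborhoods(ds, 10_000, bait_kinds=("RT",))
        w = redundancy_weights(nbs, ds)
        assert all(v == 1.0 for v in w.values())

    def test_mixed_shared_and_unique_fingerprints(self):
        # brute-force oracle: group neighborhoods by their full cluster
        # content and invert the group sizes
        ds = replicated_loci_dataset(3, 3)
        nbs = extract_neighborhoods(ds, 10_000, bait_kinds=("RT",))
        groups = {}
        for nb in nbs:
            fp = tuple(
                tuple(sorted(cluster_keys_of(ds.gene(g)))) for g in nb.member_gene_ids
            )
            groups.setdefault(fp, []).append(nb)
        expected = {}
        for members in groups.values():
            for nb in members:
                for gid in nb.member_gene_ids:
                    expected[gid] = 1.0 / len(members)
        w = redundancy_weights(nbs, ds)
        for gid, v in expected.items():
            assert w[gid] == pytest.approx(v)
        assert sorted(round(w[f"x{i}"], 4) for i in range(6)) == [
            round(x, 4) for x in (1 / 3, 1 / 3, 1 / 3, 1.0, 1.0, 1.0)
        ]


class TestIcityScore:
    def _weighted_fixture(self):
        """Members A(0.5,in), B(0.5,in), C(1.0,in), D(1.0,out) -> 2/3."""
        contigs, features, systems = {}, [], []
        # two identical loci (A, B get weight 0.5), one unique locus (C), and
        # a contig with no DGR at all (D, weight 1, outside any neighborhood)
        for i, acc_extra in enumerate(["PF00030", "PF00030", "PF00031"]):
            cid = f"c{i}"
            contigs[cid] = Contig(cid, 50_000)
            features += [
                make_gene(f"rt{i}", cid, 5_000, 6_000, "+", ["PF00078"]),
                make_gene(f"m{i}", cid, 7_000, 8_000, "+", ["PF00055", acc_extra]),
            ]
            systems.append(
                DgrSystem(cid, f"s{i}", f"rt{i}", [(5_100, 5_200, f"rt{i}")],
                          (6_100, 6_200))
            )
        contigs["c3"] = Contig("c3", 50_000)
        features.append(make_gene("m3", "c3", 7_000, 8_000, "+", ["PF00055"]))
        return dataset_of(contigs, features, systems)

    def test_weighted_sum_hand_oracle(self):
        ds = self._weighted_fixture()
        nbs = extract_neighborhoods(ds, 10_000, bait_kinds=("RT",))
        w = redundancy_weights(nbs, ds)
        score = icity_score(ClusterKey("PF00055", False), w, nbs, ds)
        assert score == pytest.approx(2.0 / 3.0)

    def test_all_members_inside_scores_one(self, toy_dataset):
        nbs = extract_neighborhoods(toy_dataset, 10_000)
        w = redundancy_weights(nbs, toy_dataset)
        assert icity_score(ClusterKey("PF05635", False), w, nbs, toy_dataset) == 1.0

    def test_no_member_inside_scores_zero(self, toy_dataset):
        nbs = extract_neighborhoods(toy_dataset, 10_000)
        w = redundancy_weights(nbs, toy_dataset)
        assert icity_score(ClusterKey("PF99999", False), w, nbs, toy_dataset) == 0.0

    def test_empty_cluster_is_an_error(self, toy_dataset):
        nbs = extract_neighborhoods(toy_dataset, 10_000)
        w = redundancy_weights(nbs, toy_dataset)
        with pytest.raises(ValueError, match="no members"):
            icity_score(ClusterKey("PF11111", False), w, nbs, toy_dataset)

    def test_brute_force_oracle_equivalence_on_small_simulation(self):
        """Position-set oracle: membership via explicit per-base coverage."""
        from dgrscout.simulate import SimConfig, simulate_dataset

        sim = simulate_dataset(
            SimConfig(n_contigs=8, seed=13, with_sequences=False,
                      background_pfam_rate=0.5, p_immune_colocalization=0.6)
        )
        ds = sim.dataset
        D = 10_000
        nbs = extract_neighborhoods(ds, D)
        w = redundancy_weights(nbs, ds)

        # oracle membership: enumerate window base positions modulo length
        covered = {}
        for nb in nbs:
            L = ds.contigs[nb.contig_id].length
            pos = {p % L for p in range(nb.window[0], nb.window[1])}
            covered.setdefault(nb.contig_id, set()).update(pos)
        in_any = set()
        for f in ds.features:
            L = ds.contigs[f.contig_id].length
            gene_pos = {p % L for p in range(f.start, f.end)}
            if gene_pos & covered.get(f.contig_id, set()):
                in_any.add(f.gene_id)

        clusters = {k for f in ds.features for k in cluster_keys_of(f)}
        for key in sorted(clusters):
            members = [f for f in ds.features if key in cluster_keys_of(f)]
            expect = sum(w[f.gene_id] for f in members if f.gene_id in in_any) / sum(
                w[f.gene_id] for f in members
            )
            assert icity_score(key, w, nbs, ds) == pytest.approx(expect)


class TestRunProtocol:
    def test_full_subsample_collapses_to_two_identical_runs(self, toy_dataset):
        table = run_icity(toy_dataset, subsample_fraction=1.0, seed=1)
        assert table.n_runs == 2
        for scores in table.run_scores.values():
            assert len(scores) == 2 and scores[0] == scores[1]

    def test_bait_self_pfam_scores_one_in_every_run(self, recovery_icity):
        rt_scores = recovery_icity.run_scores[ClusterKey("PF00078", False)]
        assert all(s == 1.0 for s in rt_scores)

    def test_planted_immune_pfam_scores_high(self, recovery_icity):
        means = recovery_icity.mean_scores()
        assert means[ClusterKey("PF01797", False)] > 0.7

    def test_invariance_to_contig_relabeling_and_strand_flip(self, toy_dataset):
        import copy

        base = run_icity(toy_dataset, subsample_fraction=1.0, seed=0).mean_scores()

        ds2 = copy.deepcopy(toy_dataset)
        relabel = {"c1": "zz9"}
        for f in ds2.features:
            f.contig_id = relabel[f.contig_id]
            f.strand = {"+": "-", "-": "+"}[f.strand]  # global strand flip
        for s in ds2.systems:
            s.contig_id = relabel[s.contig_id]
        ds2.contigs = {"zz9": Contig("zz9", 40_000)}
        ds2 = Dataset(ds2.contigs, ds2.features, ds2.systems)
        flipped = run_icity(ds2, subsample_fraction=1.0, seed=0).mean_scores()
        assert flipped == base

    def test_scores_always_within_unit_interval(self, recovery_icity):
        for scores in recovery_icity.run_scores.values():
            assert all(0.0 <= s <= 1.0 for s in scores)

    def test_mean_icity_monotone_in_colocalization_probability(self):
        from dgrscout.simulate import SimConfig, simulate_dataset

        means = []
        for p in (0.1, 0.5, 0.9):
            sim = simulate_dataset(
                SimConfig(n_contigs=150, seed=99, with_sequences=False,
                          p_immune_colocalization=p)
            )
            table = run_icity(sim.dataset, seed=17)
            means.append(table.mean_scores()[ClusterKey("PF01797", False)])
        assert means[0] <= means[1] <= means[2]


class TestSelectPfams:
    def _table(self, scores):
        from dgrscout.icity import IcityTable

        return IcityTable(
            run_scores={ClusterKey("PF00001", False): list(scores)},
            n_runs=len(scores), run_seeds=[],
        )

    key = ClusterKey("PF00001", False)

    def test_above_threshold_in_all_runs_selected_in_both_modes(self):
        t = self._table([0.8] * 7)
        assert self.key in select_pfams(t, "all_runs")
        assert self.key in select_pfams(t, "any_run")

    def test_one_low_run_drops_strict_but_not_lenient(self):
        t = self._table([0.8, 0.6, 0.8, 0.8, 0.8, 0.8, 0.8])
        assert self.key not in select_pfams(t, "all_runs")
        assert self.key in select_pfams(t, "any_run")

    def test_exactly_at_threshold_fails_strict_inequality(self):
        t = self._table([0.7] * 7)
        assert self.key not in select_pfams(t, "all_runs")
        assert self.key not in select_pfams(t, "any_run")

    def test_strict_subset_of_lenient(self, recovery_icity):
        strict = select_pfams(recovery_icity, "all_runs")
        lenient = select_pfams(recovery_icity, "any_run")
        assert strict <= lenient
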