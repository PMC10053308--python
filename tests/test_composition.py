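"""Composition filtering and gene-arrangement canonicalization."""

import itertools

import pytest

from dgrscout.composition import (
    Composition,
    arrangement_profile,
    assign_compositions,
    canonical_signature,
    possible_arrangements,
    select_compositions,
    upset_matrix,
)
from dgrscout.dataset import Dataset
from dgrscout.icity import ClusterKey, extract_neighborhoods
from dgrscout.model import Contig, DgrSystem, ImmuneCatalog

from conftest import make_gene


class TestPossibleArrangements:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 4), (3, 24), (4, 192)])
    def test_count_formula(self, n, expected):
        assert possible_arrangements(n) == expected

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            possible_arrangements(0)


class TestCanonicalSignature:
    def test_flip_symmetry(self):
        a = (("PF00001", False, "+"), ("PF00002", False, "-"))
        b = (("PF00002", False, "+"), ("PF00001", False, "-"))  # reverse + flip of a
        assert canonical_signature(a) == canonical_signature(b)

    def test_idempotent(self):
        sig = canonical_signature(
            (("PF00003", False, "-"), ("PF00001", True, "+"), ("PF00002", False, "+"))
        )
        assert canonical_signature(sig) == sig

    def test_reverse_complement_of_contig_leaves_canonical_form_unchanged(self):
        # reverse-complementing a locus = reverse gene order + flip strands
        sig = (("PF00001", False, "+"), ("PF00002", False, "+"), ("PF00003", False, "-"))
        revcomp = tuple(
            (acc, vr, {"+": "-", "-": "+"}[s]) for acc, vr, s in reversed(sig)
        )
        assert canonical_signature(sig) == canonical_signature(revcomp)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_enumeration_matches_combinatorial_count(self, n):
        """Brute force: all orders x strand choices of n labeled genes
        collapse to exactly 2^(n-1) * n! canonical classes."""
        accs = [f"PF{i:05d}" for i in range(1, n + 1)]
        forms = set()
        for perm in itertools.permutations(accs):
            for strands in itertools.product("+-", repeat=n):
                sig = tuple((a, False, s) for a, s in zip(perm, strands))
                forms.add(canonical_signature(sig))
        assert len(forms) == possible_arrangements(n)


def locus_dataset(per_locus_arrangements, immune_acc="PF01797"):
    """One contig per requested arrangement; each arrangement is a list of
    (accession, strand) laid out left to right around an RT bait."""
    contigs, features, systems = {}, [], []
    for i, arrangement in enumerate(per_locus_arrangements):
        cid = f"c{i}"
        contigs[cid] = Contig(cid, 30_000)
        features.append(make_gene(f"rt{i}", cid, 1_000, 2_000, "+", ["PF00078"]))
        pos = 3_000
        for j, (acc, strand) in enumerate(arrangement):
            features.append(
                make_gene(f"g{i}_{j}", cid, pos, pos + 600, strand, [acc])
            )
            pos += 800
        systems.append(
            DgrSystem(cid, f"s{i}", f"rt{i}", [(1_100, 1_200, f"rt{i}")], (2_100, 2_200))
        )
    return Dataset.assemble(contigs, features, systems)


SEL = {
    ClusterKey("PF00078", False),
    ClusterKey("PF01797", False),
    ClusterKey("PF00002", False),
}
CATALOG = ImmuneCatalog(["PF01797"])


class TestAssignCompositions:
    def test_locus_key_is_selected_clusters_with_immune_flagging(self):
        ds = locus_dataset([[("PF01797", "+"), ("PF00002", "+")]])
        comps = assign_compositions(ds, SEL, CATALOG)
        assert len(comps) == 1
        # the RT gene hosts the VR here, so its cluster is (PF00078, vr=True)
        # and only the two selected non-VR clusters enter the key
        assert comps[0].key == frozenset(
            {ClusterKey("PF01797", False), ClusterKey("PF00002", False)}
        )
        assert comps[0].n_occurrences == 1

    def test_locus_without_immune_pfam_is_dropped(self):
        ds = locus_dataset([[("PF00002", "+")]])
        assert assign_compositions(ds, SEL, CATALOG) == []

    def test_vr_and_non_vr_of_same_family_are_distinct_members(self):
        ds = locus_dataset([[("PF01797", "+"), ("PF00002", "+")]])
        # mark one PF00002 gene as VR-hosting and add a plain PF00002 peer
        ds.features.append(make_gene("extra", "c0", 6_000, 6_600, "+", ["PF00002"]))
        ds.gene("g0_1").contains_vr = True
        ds = Dataset(ds.contigs, ds.features, ds.systems)
        selected = SEL | {ClusterKey("PF00002", True)}
        comps = assign_compositions(ds, selected, CATALOG)
        assert ClusterKey("PF00002", True) in comps[0].key
        assert ClusterKey("PF00002", False) in comps[0].key

    def test_identical_keys_merge_with_counts(self):
        ds = locus_dataset([[("PF01797", "+")]] * 3)
        comps = assign_compositions(ds, SEL, CATALOG)
        assert len(comps) == 1 and comps[0].n_occurrences == 3


class TestSelectCompositions:
    @pytest.mark.parametrize(
        "occ,long,kept",
        [(25, 5, True), (20, 5, False), (30, 3, False), (21, 4, True)],
    )
    def test_occurrence_and_long_contig_thresholds(self, occ, long, kept):
        comp = Composition(
            key=frozenset({ClusterKey("PF01797", False)}),
            n_occurrences=occ, n_long_contigs=long,
        )
        assert (comp in select_compositions([comp])) is kept

    def test_order_independent(self):
        comps = [
            Composition(frozenset({ClusterKey(f"PF{i:05d}", False)}),
                        n_occurrences=25, n_long_contigs=5)
            for i in range(5)
        ]
        a = select_compositions(comps)
        b = select_compositions(list(reversed(comps)))
        assert {c.label() for c in a} == {c.label() for c in b}


class TestArrangementProfile:
    def _profile(self, arrangements):
        ds = locus_dataset(arrangements)
        comps = assign_compositions(ds, SEL, CATALOG)
        assert len(comps) == 1
        return arrangement_profile(comps[0], ds)

    def test_identical_loci_give_modal_fraction_one(self):
        p = self._profile([[("PF01797", "+"), ("PF00002", "+")]] * 4)
        assert p.modal_fraction == 1.0 and len(p.counts) == 1

    def test_two_distinct_arrangements_split_evenly(self):
        p = self._profile(
            [
                [("PF01797", "+"), ("PF00002", "+")],
                [("PF00002", "+"), ("PF01797", "+")],
            ]
        )
        assert p.modal_fraction == 0.5 and len(p.counts) == 2

    def test_flipped_reading_counts_as_same_arrangement(self):
        p = self._profile(
            [
                [("PF01797", "+"), ("PF00002", "-")],
                [("PF00002", "+"), ("PF01797", "-")],  # reverse-complement image
            ]
        )
        assert p.modal_fraction == 1.0

    def test_conservation_recovery_on_simulation(self):
        from dgrscout.icity import run_icity, select_pfams
        from dgrscout.simulate import SimConfig, simulate_dataset

        conserved = 0.98
        n = 500
        sim = simulate_dataset(
            SimConfig(n_contigs=n, seed=3, with_sequences=False,
                      p_immune_colocalization=1.0, background_pfam_rate=0.0,
                      arrangement_conservation=conserved)
        )
        table = run_icity(sim.dataset, seed=5)
        comps = assign_compositions(
            sim.dataset, select_pfams(table), sim.immune_catalog
        )
        assert len(comps) == 1 and comps[0].n_occurrences == n
        p = arrangement_profile(comps[0], sim.dataset)
        se = (conserved * (1 - conserved) / n) ** 0.5
        assert abs(p.modal_fraction - conserved) < 3 * se

    def test_planted_keys_recovered_exactly_without_decoys(self):
        from dgrscout.icity import run_icity, select_pfams
        from dgrscout.simulate import SimConfig, simulate_dataset

        sim = simulate_dataset(
            SimConfig(n_contigs=60, seed=21, with_sequences=False,
                      p_immune_colocalization=1.0, background_pfam_rate=0.0)
        )
        table = run_icity(sim.dataset, seed=2)
        comps = assign_compositions(
            sim.dataset, select_pfams(table), sim.immune_catalog
        )
        planted = set(sim.ground_truth.planted_composition.unique())
        assert {c.label() for c in comps} == planted


class TestUpsetMatrix:
    def test_membership_matrix_marks_key_members(self):
        comps = [
            Composition(frozenset({ClusterKey("PF00001", False),
                                   ClusterKey("PF00002", False)}),
                        n_occurrences=5),
            Composition(frozenset({ClusterKey("PF00001", False)}), n_occurrences=9),
        ]
        m = upset_matrix(comps).set_index("composition")
        assert m.loc["PF00001+PF00002", "PF00001"] == 1
        assert m.loc["PF00001", "PF00002"] == 0
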