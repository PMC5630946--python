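"""Generator invariants: master structure, substitution process, planting."""

import math

import numpy as np
import pytest
import scipy.linalg

from tc1kit import (ParameterError, build_master_element, find_sir, find_tir,
                    locate_triad, mutate_sequence, pairwise_distance,
                    plant_copies, reverse_complement, simulate_ht_scenario,
                    spacing_label)
from tc1kit.synth import SpeciesTree, TruthTable, _random_dna


class TestMasterElement:
    def test_structural_invariants(self, master):
        t = master.tir_length
        assert master.sequence[:t] == \
            reverse_complement(master.sequence[-t:])
        s, e = master.orf_interval
        assert (e - s) % 3 == 0
        assert "*" not in master.protein
        assert len(master.sequence) == 1563
        assert len(master.protein) == 338

    def test_triad_spacing_built_in(self, master):
        tri = locate_triad(master.protein)
        assert tri is not None
        assert tri.spacing == 37
        assert spacing_label(tri) == "DD37E"

    def test_deterministic_given_seed(self):
        a = build_master_element(seed=42)
        b = build_master_element(seed=42)
        assert a.sequence == b.sequence
        assert a.sir == b.sir

    def test_degenerate_zero_spacing(self):
        m = build_master_element(orf_codons=120, dde_spacing=0, seed=1,
                                 length=800)
        d1, d2, e = m.triad_positions
        prot = m.protein
        assert prot[d1] == "D" and prot[d2] == "D" and prot[e] == "E"
        assert e - d2 - 1 == 0

    def test_unachievable_spacing_raises(self):
        with pytest.raises(ParameterError):
            build_master_element(orf_codons=40, dde_spacing=37)
        with pytest.raises(ParameterError):
            build_master_element(tir_length=5)

    def test_detectors_recover_planted_geometry(self):
        for seed in range(5):
            m = build_master_element(tir_length=27, dde_spacing=37,
                                     seed=seed)
            tir = find_tir(m.sequence)
            assert tir.length == 27 and tir.mismatches == 0
            sir = find_sir(m.sequence, tir)
            assert sir.length == 23
            assert m.sequence[sir.left_start:sir.left_end] == m.sir[0]


class TestMutateSequence:
    def test_zero_divergence_identity(self, master):
        assert mutate_sequence(master.sequence, 0.0, seed=1) == \
            master.sequence

    def test_out_of_range_divergence(self):
        with pytest.raises(ParameterError):
            mutate_sequence("ACGT", 0.8)

    def test_observed_p_matches_k2p_saturation_curve(self):
        """Mean difference fraction equals the multiple-hit-corrected
        expectation from the K2P rate matrix (within 3 SE)."""
        d, kappa, L, reps = 0.05, 2.0, 10_000, 200
        a = kappa / (kappa + 2)
        b = (1 - a) / 2
        Q = np.array([[-1, b, a, b], [b, -1, b, a],
                      [a, b, -1, b], [b, a, b, -1]])
        p_expected = 1 - scipy.linalg.expm(Q * d)[0, 0]
        ref = "ACGT" * (L // 4)
        obs = []
        for s in range(reps):
            mut = mutate_sequence(ref, d, kappa, seed=s)
            obs.append(sum(x != y for x, y in zip(ref, mut)) / L)
        se = np.std(obs, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(obs) - p_expected) < 3 * se + 1e-12

    def test_infinite_kappa_only_transitions(self):
        ref = "ACGT" * 2500
        mut = mutate_sequence(ref, 0.05, float("inf"), seed=1)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        diffs = [(x, y) for x, y in zip(ref, mut) if x != y]
        assert diffs and all(d in transitions for d in diffs)

    def test_length_preserved_and_ns_untouched(self):
        seq = "ACGTN" * 100
        mut = mutate_sequence(seq, 0.3, seed=2)
        assert len(mut) == len(seq)
        assert all(m == "N" for m, s in zip(mut, seq) if s == "N")


class TestPlantCopies:
    def test_zero_copies_noop(self, master):
        g = "ACGTA" * 100
        out, truth = plant_copies(g, master, 0, seed=1)
        assert out == g and truth.planted_copies == []

    def test_exact_fraction_assignment(self, master):
        rng = np.random.default_rng(0)
        host = _random_dna(rng, 1_000_000)
        _, truth = plant_copies(host, master, 44, divergence=0.05,
                                truncate_frac=0.5, inactivate_frac=0.0,
                                seed=9)
        full = sum(c.truncated is None for c in truth.planted_copies)
        assert len(truth.planted_copies) == 44
        assert full == 22  # round(44 * 0.5) truncated, rest full-length

    def test_tsd_flanks_match_truncation_state(self, planted_dataset):
        genome, truth = planted_dataset
        for c in truth.planted_copies:
            left = genome[c.start - 2:c.start]
            right = genome[c.end:c.end + 2]
            flanked = left == "TA" and right == "TA"
            assert flanked == (c.truncated is None)

    def test_round_trip_identity_of_untruncated_copies(
            self, master, planted_dataset):
        genome, truth = planted_dataset
        for c in truth.planted_copies:
            if c.truncated is not None or c.inactivated:
                continue
            seq = genome[c.start:c.end]
            if c.strand == "-":
                seq = reverse_complement(seq)
            p = pairwise_distance(seq, master.sequence, "p")
            # ~2% divergence planted; 3 SE of binomial sampling
            se = math.sqrt(0.02 * 0.98 / len(seq))
            assert abs(p - 0.02) < 3 * se + 0.005

    def test_deterministic_given_seed(self, master):
        host = _random_dna(np.random.default_rng(1), 50_000)
        g1, t1 = plant_copies(host, master, 5, seed=3)
        g2, t2 = plant_copies(host, master, 5, seed=3)
        assert g1 == g2
        assert t1.to_json() == t2.to_json()

    def test_truth_table_json_round_trip(self, planted_dataset):
        _, truth = planted_dataset
        again = TruthTable.from_json(truth.to_json())
        assert again.seed == truth.seed
        assert again.planted_copies == truth.planted_copies


class TestSpeciesTree:
    def test_ultrametric_ages(self):
        st = SpeciesTree.from_newick("((A:4,B:4):15.6,C:19.6);")
        assert st.root_age == pytest.approx(19.6)
        assert st.mrca_age(["A", "B"]) == pytest.approx(4.0)
        assert st.mrca_age(["A", "C"]) == pytest.approx(19.6)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTree.from_newick("((A:4,B:7):15.6,C:19.6);")

    def test_unknown_tip_rejected(self):
        st = SpeciesTree.from_newick("((A:4,B:4):15.6,C:19.6);")
        with pytest.raises(ValueError):
            st.mrca_age(["A", "Z"])


class TestHTScenario:
    def test_transferred_te_distance_scales_with_event_time(self):
        """HT at 5 Ma between lineages split 110 Ma: expected TE distance
        is (10/220) of the marker distance (both evolve at equal rate)."""
        rate = 0.0015
        sc = simulate_ht_scenario("(X:110,Y:110);", rate, rate,
                                  [("X", "Y", 5.0)], seed=11,
                                  genome_length=0)
        d_te = pairwise_distance(sc.te_sequences["X"], sc.te_sequences["Y"])
        d_mk = pairwise_distance(sc.markers["X"], sc.markers["Y"])
        assert d_te == pytest.approx(2 * rate * 5, abs=0.01)
        assert d_mk == pytest.approx(2 * rate * 110, rel=0.15)
        assert d_te < 0.2 * d_mk

    def test_vertical_null_distances_match(self):
        rate = 0.0015
        sc = simulate_ht_scenario("(X:110,Y:110);", rate, rate, [],
                                  seed=12, genome_length=0)
        d_te = pairwise_distance(sc.te_sequences["X"], sc.te_sequences["Y"])
        d_mk = pairwise_distance(sc.markers["X"], sc.markers["Y"])
        assert d_te == pytest.approx(d_mk, rel=0.25)

    def test_unknown_tip_in_event_rejected(self):
        with pytest.raises(ValueError):
            simulate_ht_scenario("(X:110,Y:110);", 0.001, 0.001,
                                 [("X", "Z", 5.0)], genome_length=0)

    def test_genomes_carry_planted_copies(self):
        sc = simulate_ht_scenario("(X:20,Y:20);", 0.0015, 0.0015, [],
                                  seed=13, copies_per_species=2,
                                  genome_length=30_000)
        per_species = {}
        for c in sc.truth.planted_copies:
            per_species.setdefault(c.species, 0)
            per_species[c.species] += 1
        assert per_species == {"X": 2, "Y": 2}
        for c in sc.truth.planted_copies:
            g = sc.genomes[c.species]
            assert 0 <= c.start < c.end <= len(g)
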