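"""Star alignment, consensus reconstruction, ORF finding and intactness."""

import numpy as np
import pytest

from tc1kit import (align_copies, annotate_copies, build_consensus,
                    check_intact, classify_full_length, family_counts,
                    find_orf, mutate_sequence, pairwise_distance,
                    plant_copies, reverse_complement)
from tc1kit.consensus import CopyAlignment, element_boundaries, \
    pick_reference, slice_columns
from tc1kit.synth import _CODONS, _random_dna


def _brute_force_longest_orf(seq, min_codons):
    """Independent all-ORFs oracle: stop-to-stop in six frames, trimmed
    to the first ATG (untrimmed if none), longest wins with the same
    tie order as the implementation contract (+ strand, low frame,
    leftmost)."""
    from Bio.Seq import Seq
    best = None
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for f in range(3):
            codons = [s[i:i + 3] for i in range(f, len(s) - 2, 3)]
            aas = [str(Seq(c).translate()) for c in codons]
            seg_start = 0
            segments = []
            for i, aa in enumerate(aas + ["*"]):
                if aa == "*":
                    segments.append((seg_start, i))
                    seg_start = i + 1
            for a, b in segments:
                seg = "".join(aas[a:b])
                m = seg.find("M")
                if m >= 0:
                    cand, c_start = seg[m:], a + m
                else:
                    cand, c_start = seg, a
                if len(cand) < min_codons:
                    continue
                nt_lo = f + 3 * c_start
                nt_hi = nt_lo + 3 * len(cand)
                coords = (nt_lo, nt_hi) if strand == "+" else \
                    (L - nt_hi, L - nt_lo)
                if best is None or len(cand) > len(best[3]):
                    best = (coords[0], coords[1], strand, cand)
    return best


class TestAlignCopies:
    def test_identical_sequences_no_gaps(self):
        aln = align_copies({"a": "ACGTACGT", "b": "ACGTACGT",
                            "c": "ACGTACGT"})
        assert aln.n_columns == 8
        assert all("-" not in r for r in aln.rows)

    def test_degapped_rows_reproduce_inputs(self, master):
        seqs = {f"c{i}": mutate_sequence(master.sequence, 0.05,
                                         seed=300 + i)
                for i in range(5)}
        aln = align_copies(seqs)
        for sid, seq in seqs.items():
            assert aln.row(sid).replace("-", "") == seq

    def test_column_count_close_to_master_length(self, master):
        seqs = {f"c{i}": mutate_sequence(master.sequence, 0.05,
                                         seed=400 + i)
                for i in range(8)}
        aln = align_copies(seqs)
        assert abs(aln.n_columns - len(master.sequence)) \
            <= 0.01 * len(master.sequence)

    def test_internal_deletion_becomes_gap_block(self, master):
        ref = master.sequence
        deleted = ref[:700] + ref[750:]
        aln = align_copies({"ref": ref, "del": deleted})
        row = aln.row("del")
        assert row.count("-") == 50
        assert max(_gap_runs(row), default=0) == 50

    def test_single_sequence_identity_alignment(self):
        aln = align_copies({"only": "ACGT"})
        assert aln.rows == ["ACGT"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            align_copies([("a", "ACGT"), ("a", "ACGT")])


def _gap_runs(row):
    runs, n = [], 0
    for ch in row:
        if ch == "-":
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


class TestBuildConsensus:
    def test_identical_rows_idempotent(self):
        aln = CopyAlignment(["a", "b", "c"], ["ACGT"] * 3, "a")
        assert build_consensus(aln) == "ACGT"

    def test_majority_column(self):
        aln = CopyAlignment(["a", "b", "c"], ["A", "A", "G"], "c")
        assert build_consensus(aln) == "A"

    def test_tie_breaks_toward_reference(self):
        aln = CopyAlignment(["a", "b"], ["A", "G"], "b")
        assert build_consensus(aln) == "G"

    def test_low_occupancy_columns_dropped(self):
        aln = CopyAlignment(["a", "b", "c", "d"],
                            ["ACGT", "ACGT", "A-GT", "-----"[:4]], "a")
        # last row all gaps: occupancy 0.75 per column except col 1 (0.5)
        assert build_consensus(aln, min_col_occupancy=0.7) == "AGT"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(CopyAlignment([], [], "x"))

    def test_recovery_from_20_copies_at_5pct(self, master):
        seqs = {f"c{i}": mutate_sequence(master.sequence, 0.05,
                                         seed=500 + i)
                for i in range(20)}
        aln = align_copies(seqs)
        consensus = build_consensus(aln)
        assert len(consensus) == len(master.sequence)
        p = pairwise_distance(consensus, master.sequence, "p")
        assert p <= 0.01


class TestElementBoundaries:
    def test_flanked_copies_trimmed_to_element(self, master):
        rng = np.random.default_rng(31)
        seqs = {}
        for i in range(8):
            flank_l = _random_dna(rng, 300)
            flank_r = _random_dna(rng, 300)
            seqs[f"c{i}"] = flank_l + mutate_sequence(
                master.sequence, 0.02, seed=600 + i) + flank_r
        aln = align_copies(seqs, reference=pick_reference(seqs))
        lo, hi = element_boundaries(aln)
        consensus = build_consensus(slice_columns(aln, lo, hi))
        # recovered block covers the element, up to pad-width slack
        assert abs(len(consensus) - len(master.sequence)) <= 10
        assert master.sequence[100:200] in consensus

    def test_single_row_returns_everything(self):
        aln = CopyAlignment(["a"], ["ACGTACGT"], "a")
        assert element_boundaries(aln) == (0, 8)


class TestClassifyFullLength:
    def test_high_identity_full_coverage(self, master):
        copy = mutate_sequence(master.sequence, 0.02, seed=1)
        full, ident, cov = classify_full_length(copy, master.sequence)
        assert full and ident > 0.95 and cov > 0.99

    def test_identity_below_threshold(self, master):
        copy = mutate_sequence(master.sequence, 0.10, seed=2)
        full, ident, cov = classify_full_length(copy, master.sequence)
        assert not full and ident < 0.95

    def test_truncated_copy_fails_coverage(self, master):
        copy = master.sequence[:len(master.sequence) // 2]
        full, ident, cov = classify_full_length(copy, master.sequence)
        assert not full and ident > 0.95 and cov < 0.6


class TestFindOrf:
    def test_master_coding_region_338aa(self, master):
        orf = find_orf(master.sequence)
        assert orf.n_codons == 338
        assert (orf.start, orf.end) == master.orf_interval
        assert orf.end - orf.start == 1014

    def test_stop_riddled_sequence_empty(self):
        # "TTAATTAATTAA" carries a stop in every one of the six frames
        # (it is its own reverse complement), so no ORF can qualify
        assert find_orf("TTAATTAATTAA" * 50, min_codons=50) is None

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_orf("ATG", min_codons=10)

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(71)
        for _ in range(60):
            seq = _random_dna(rng, 2000)
            got = find_orf(seq, min_codons=20)
            exp = _brute_force_longest_orf(seq, 20)
            if exp is None:
                assert got is None
            else:
                assert (got.start, got.end, got.strand, got.protein) == exp


class TestCheckIntact:
    def test_clean_copy_true(self, master):
        mut = mutate_sequence(master.sequence, 0.02, seed=3)
        from tc1kit.synth import _repair_orf
        mut = _repair_orf(mut, master)
        orf = find_orf(mut)
        assert check_intact(orf.protein, master.protein)

    def test_short_orf_false(self, master):
        assert not check_intact(master.protein[:250], master.protein)

    def test_internal_stop_false(self, master):
        prot = master.protein[:150] + "*" + master.protein[151:]
        assert not check_intact(prot, master.protein)

    def test_frameshift_detected_from_cds(self, master):
        s, e = master.orf_interval
        cds = master.sequence[s:e]
        shifted = cds[:500] + cds[501:]  # 1-bp deletion
        assert not check_intact(master.protein, master.protein,
                                copy_cds=shifted, reference_cds=cds)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            check_intact("MAA", "")


class TestAnnotateCopies:
    def test_planted_intact_counts_exact(self, master):
        """201 full-length copies with 84 clean ORFs planted -> 84
        intact calls (117 copies carry a stop codon or 1-bp deletion)."""
        rng = np.random.default_rng(81)
        host = _random_dna(rng, 700_000)
        genome, truth = plant_copies(
            host, master, 201, divergence=0.02, truncate_frac=0.0,
            inactivate_frac=117 / 201, seed=15, min_spacing=800)
        copies = [(f"c{i}", _copy_seq(genome, c))
                  for i, c in enumerate(truth.planted_copies)]
        annotated = annotate_copies(copies, master.sequence,
                                    master.protein,
                                    consensus_orf=master.orf_interval)
        counts = family_counts(annotated)
        assert counts["copies"] == 201
        assert counts["full_length"] == 201
        assert counts["intact"] == 84

    def test_flag_consistency_invariant(self, master, planted_dataset):
        genome, truth = planted_dataset
        copies = [(f"c{i}", _copy_seq(genome, c))
                  for i, c in enumerate(truth.planted_copies)]
        annotated = annotate_copies(copies, master.sequence,
                                    master.protein,
                                    consensus_orf=master.orf_interval)
        for a in annotated:
            assert not (a.intact_orf and not a.full_length)
        counts = family_counts(annotated)
        assert counts["intact"] <= counts["full_length"] \
            <= counts["copies"]


def _copy_seq(genome, planted):
    seq = genome[planted.start:planted.end]
    return reverse_complement(seq) if planted.strand == "-" else seq
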