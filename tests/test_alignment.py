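"""Alignment, identity and numbering-transfer tests.

The affine-gap aligner is cross-checked two ways: exhaustive enumeration of
every possible global alignment on tiny inputs, and score agreement with an
independent dynamic-programming implementation (Biopython's
PairwiseAligner) on random sequences.
"""

import numpy as np
import pytest

from granzymekit import SequenceRecord
from granzymekit.align import (
    AlignmentError,
    AlignParams,
    LowCoverageError,
    build_identity_matrix,
    build_numbering_map,
    global_align,
    global_align_strings,
    percent_identity,
    progressive_msa,
)
from granzymekit.synthetic import ScaffoldSpec, make_scaffold

from conftest import random_dna, random_protein

GO, GE = 10.0, 0.5


def _affine_score(ops, seq_a, seq_b, scorer):
    """Score an op string (M/X/Y) under the package's gap convention:
    first gap residue costs open, subsequent residues cost extend."""
    total, i, j, prev = 0.0, 0, 0, None
    for op in ops:
        if op == "M":
            total += scorer(seq_a[i], seq_b[j])
            i += 1
            j += 1
        else:
            total -= GE if prev == op else GO
            if op == "X":
                i += 1
            else:
                j += 1
        prev = op
    return total


def _enumerate_alignments(n, m):
    """Every global alignment of lengths n x m as an op string."""
    if n == 0 and m == 0:
        yield ""
        return
    if n > 0:
        for rest in _enumerate_alignments(n - 1, m):
            yield "X" + rest
    if m > 0:
        for rest in _enumerate_alignments(n, m - 1):
            yield "Y" + rest
    if n > 0 and m > 0:
        for rest in _enumerate_alignments(n - 1, m - 1):
            yield "M" + rest


class TestGlobalAlign:
    def test_identical_iigg_scores_blosum_diagonal(self):
        a = SequenceRecord("a", "protein", "IIGG")
        b = SequenceRecord("b", "protein", "IIGG")
        aln = global_align(a, b)
        assert "-" not in aln.row("a") + aln.row("b")
        # BLOSUM62 diagonal: I=4, G=6
        assert aln.score == pytest.approx(4 + 4 + 6 + 6)

    def test_dna_gap_placement_matches_exhaustive_optimum(self):
        """ACGT vs AGT under +5/-4: enumeration confirms one-gap optimum."""
        a, b = "ACGT", "AGT"
        scorer = AlignParams().scorer("dna")
        best = max(
            _affine_score(ops, a, b, scorer)
            for ops in _enumerate_alignments(len(a), len(b))
        )
        aln = global_align_strings("a", a, "b", b, "dna")
        assert aln.score == pytest.approx(best)
        assert aln.row("b").count("-") == 1
        assert aln.row("a") == "ACGT"

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_aligner_score(self, seed):
        from Bio.Align import PairwiseAligner, substitution_matrices

        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(8, 40)))
        b = random_protein(rng, int(rng.integers(8, 40)))
        ours = global_align_strings("a", a, "b", b, "protein").score
        aligner = PairwiseAligner(
            mode="global", open_gap_score=-GO, extend_gap_score=-GE,
            substitution_matrix=substitution_matrices.load("BLOSUM62"))
        assert ours == pytest.approx(aligner.score(a, b))

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(AlignmentError, match="mixed"):
            global_align(SequenceRecord("a", "protein", "MKT"),
                         SequenceRecord("b", "dna", "ACG"))

    def test_empty_sequence_policy(self):
        with pytest.raises(AlignmentError, match="empty"):
            global_align_strings("a", "", "b", "ACGT", "dna")
        aln = global_align_strings("a", "", "b", "ACGT", "dna",
                                   AlignParams(empty_policy="allow"))
        assert aln.row("a") == "----"

    @pytest.mark.parametrize("seed", range(4))
    def test_score_invariant_under_argument_swap(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = SequenceRecord("a", "dna", random_dna(rng, 30))
        b = SequenceRecord("b", "dna", random_dna(rng, 25))
        fwd = global_align(a, b)
        rev = global_align(b, a)
        assert fwd.score == pytest.approx(rev.score)
        assert fwd.row("a") == rev.row("a")
        assert fwd.row("b") == rev.row("b")

    def test_gap_removal_recovers_inputs(self):
        rng = np.random.default_rng(7)
        a = SequenceRecord("a", "protein", random_protein(rng, 35))
        b = SequenceRecord("b", "protein", random_protein(rng, 28))
        aln = global_align(a, b)
        assert aln.ungapped("a") == a.residues
        assert aln.ungapped("b") == b.residues


class TestProgressiveMsa:
    def test_identical_sequences_align_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "protein", "MKTAYIAKQR")
                for i in range(3)]
        aln = progressive_msa(recs)
        assert all("-" not in s for _, s in aln.rows)

    def test_two_records_reduce_to_pairwise(self):
        rng = np.random.default_rng(3)
        a = SequenceRecord("a", "protein", random_protein(rng, 30))
        b = SequenceRecord("b", "protein", random_protein(rng, 26))
        msa = progressive_msa([a, b])
        pair = global_align(a, b)
        assert msa.rows == pair.rows

    def test_planted_indel_confined_to_one_gap_block(self):
        rng = np.random.default_rng(11)
        scaffold = random_protein(rng, 60)
        with_insert = scaffold[:30] + "WWW" + scaffold[30:]
        recs = [
            SequenceRecord("a", "protein", scaffold),
            SequenceRecord("b", "protein", scaffold),
            SequenceRecord("c", "protein", with_insert),
            SequenceRecord("d", "protein", scaffold),
        ]
        aln = progressive_msa(recs)
        for rid in "abd":
            row = aln.row(rid)
            assert row.count("-") == 3
            start = row.index("-")
            assert row[start:start + 3] == "---"
        assert "-" not in aln.row("c")

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(AlignmentError):
            progressive_msa([SequenceRecord("a", "protein", "MKT")])

    def test_many_copies_stay_gap_free(self):
        recs = [SequenceRecord(f"s{i}", "dna", "ACGTACGTAC")
                for i in range(6)]
        aln = progressive_msa(recs)
        assert all("-" not in s for _, s in aln.rows)


class TestPercentIdentity:
    def test_identical_rows_are_100(self):
        from granzymekit.align import Alignment

        aln = Alignment((("a", "M" * 50), ("b", "M" * 50)))
        assert percent_identity(aln, "a", "b") == 100.0

    def test_nine_of_ten_matches(self):
        from granzymekit.align import Alignment

        aln = Alignment((("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQW")))
        assert percent_identity(aln, "a", "b") == pytest.approx(90.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = SequenceRecord("a", "protein", random_protein(rng, 40))
        b = SequenceRecord("b", "protein", random_protein(rng, 40))
        aln = global_align(a, b)
        assert percent_identity(aln, "a", "b") == \
            pytest.approx(percent_identity(aln, "b", "a"))

    def test_terminal_overhangs_excluded_in_aligned_columns_mode(self):
        from granzymekit.align import Alignment

        aln = Alignment((("a", "MMKT---"), ("b", "--KTWWW")))
        # counted region is columns 3-4 (KT vs KT)
        assert percent_identity(aln, "a", "b", mode="aligned_columns") == 100.0
        assert percent_identity(aln, "a", "b", mode="shorter_seq") == \
            pytest.approx(100.0 * 2 / 4)

    def test_zero_denominator_raises(self):
        from granzymekit.align import Alignment

        aln = Alignment((("a", "MM--"), ("b", "--KT")))
        with pytest.raises(AlignmentError, match="denominator"):
            percent_identity(aln, "a", "b")

    def test_similarity_counts_positive_scores(self):
        from granzymekit.align import Alignment

        # I/L scores +2 in BLOSUM62 (similar), I/P scores -3
        aln = Alignment((("a", "II"), ("b", "LP")))
        assert percent_identity(aln, "a", "b", metric="similarity") == 50.0


class TestIdentityMatrix:
    def test_invariants_on_random_records(self):
        rng = np.random.default_rng(9)
        recs = [SequenceRecord(f"s{i}", "protein", random_protein(rng, 50))
                for i in range(4)]
        im = build_identity_matrix(recs)
        assert np.allclose(im.identity, im.identity.T)
        assert np.allclose(np.diag(im.identity), 100.0)
        assert im.identity.min() >= 0 and im.identity.max() <= 100
        assert np.all(im.similarity >= im.identity - 1e-9)


class TestNumberingMap:
    def test_reference_to_itself_is_identity(self, chymo):
        ref, nums = chymo
        nmap = build_numbering_map(ref, ref, nums)
        assert nmap.assignments == {i: i for i in range(1, len(nums) + 1)}

    def test_deletion_preserves_downstream_numbers(self, chymo):
        ref, nums = chymo
        # delete residues 90-91: numbers <90 unchanged, >=92 preserved
        deleted = ref.residues[:89] + ref.residues[91:]
        query = SequenceRecord("del2", "protein", deleted)
        nmap = build_numbering_map(query, ref, nums)
        inv = nmap.inverse()
        assert inv[89] == 89
        assert 90 not in inv and 91 not in inv
        assert inv[92] == 90
        assert inv[245] == 243

    def test_scaffold_triad_positions_recovered(self, chymo, scaffold_mature):
        ref, nums = chymo
        nmap = build_numbering_map(scaffold_mature, ref, nums)
        assert nmap.residue_at(scaffold_mature, 57) == "H"
        assert nmap.residue_at(scaffold_mature, 102) == "D"
        assert nmap.residue_at(scaffold_mature, 195) == "S"

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonic_and_injective_on_mutated_scaffolds(self, chymo, seed):
        ref, nums = chymo
        _, truth = make_scaffold(ScaffoldSpec(seed=seed, mutation_rate=0.15))
        query = SequenceRecord("q", "protein", truth.mature)
        nmap = build_numbering_map(query, ref, nums)
        values = list(nmap.assignments.values())
        assert values == sorted(values)
        assert len(values) == len(set(values))

    def test_low_coverage_raises_then_warns(self, chymo):
        ref, nums = chymo
        query = SequenceRecord("short", "protein", ref.residues[:40])
        with pytest.raises(LowCoverageError):
            build_numbering_map(query, ref, nums)
        with pytest.warns(UserWarning):
            build_numbering_map(query, ref, nums, strict=False)
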