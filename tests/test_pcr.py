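"""In-silico PCR and exon-skipping tests."""

import numpy as np
import pytest

from granzymekit import GeneModel, PrimerPair, SequenceRecord
from granzymekit.pcr import (
    AmbiguousPrimingError,
    PcrError,
    assemble_transcript,
    contiguous_internal_skip_sets,
    insilico_pcr,
    reverse_complement,
    splice_variant_scan,
)
from granzymekit.synthetic import make_gene_fixture

from conftest import random_dna


@pytest.fixture(scope="module")
def fixture():
    return make_gene_fixture(n_exons=5, exon_lengths=201, seed=17,
                             triad_exon=4)


class TestAssembleTranscript:
    def test_full_transcript_length_is_exon_sum(self, fixture):
        tx = assemble_transcript(fixture.model, fixture.genome)
        assert len(tx.residues) == sum(
            e - s + 1 for s, e in fixture.model.exons)

    def test_skipping_middle_exon(self):
        genome = SequenceRecord("g", "dna", "A" * 10 + "C" * 10 + "G" * 10
                                + "T" * 10 + "A" * 10)
        model = GeneModel("m", "g", "+", ((1, 10), (21, 30), (41, 50)))
        tx = assemble_transcript(model, genome, skipped={2})
        assert tx.residues == "A" * 10 + "A" * 10

    def test_minus_strand_single_exon_is_reverse_complement(self):
        genome = SequenceRecord("g", "dna", "AACCGGTTAACC")
        model = GeneModel("m", "g", "-", ((3, 8),))
        tx = assemble_transcript(model, genome)
        assert tx.residues == reverse_complement("CCGGTT")

    def test_minus_strand_exon_order_follows_transcript(self):
        genome = SequenceRecord("g", "dna", "AAAATTTTGGGGCCCC")
        model = GeneModel("m", "g", "-", ((1, 4), (9, 12)))
        tx = assemble_transcript(model, genome)
        # transcript order: genomic-last exon first, each revcomped
        assert tx.residues == reverse_complement("GGGG") + \
            reverse_complement("AAAA")

    def test_skipping_all_exons_rejected(self):
        genome = SequenceRecord("g", "dna", "ACGTACGTAC")
        model = GeneModel("m", "g", "+", ((1, 4), (7, 10)))
        with pytest.raises(PcrError, match="all exons"):
            assemble_transcript(model, genome, skipped={1, 2})


class TestInsilicoPcr:
    def test_amplicon_length_arithmetic(self):
        rng = np.random.default_rng(5)
        fwd = random_dna(rng, 20)
        rev = random_dna(rng, 21)
        template = SequenceRecord(
            "t", "dna", fwd + random_dna(rng, 100) + reverse_complement(rev))
        result = insilico_pcr(template, PrimerPair("p", fwd, rev))
        assert result.amplicon_length == 20 + 100 + 21
        assert result.forward_hit == (1, 0)

    def test_missing_reverse_site_gives_no_amplicon(self):
        rng = np.random.default_rng(6)
        fwd = random_dna(rng, 20)
        template = SequenceRecord("t", "dna", fwd + random_dna(rng, 100))
        result = insilico_pcr(template, PrimerPair("p", fwd, random_dna(rng, 20)))
        assert result.functional_call == "no_amplicon"
        assert result.amplicon_length is None

    def test_strand_consistency(self):
        rng = np.random.default_rng(7)
        fwd, rev = random_dna(rng, 20), random_dna(rng, 20)
        template = SequenceRecord(
            "t", "dna", fwd + random_dna(rng, 80) + reverse_complement(rev))
        flipped = SequenceRecord(
            "t_rc", "dna", reverse_complement(template.residues))
        a = insilico_pcr(template, PrimerPair("p", fwd, rev))
        b = insilico_pcr(flipped, PrimerPair("p", rev, fwd))
        assert a.amplicon_length == b.amplicon_length

    def test_iupac_primer_codes_match_expansions(self):
        # forward primer starting with R matches templates starting A or G
        rng = np.random.default_rng(10)
        core = random_dna(rng, 15)
        rev = random_dna(rng, 15)
        pair = PrimerPair("p", "R" + core[:9], rev)
        for base in "AG":
            template = SequenceRecord(
                "t", "dna",
                base + core + "TTTT" + reverse_complement(rev))
            result = insilico_pcr(template, pair)
            assert result.forward_hit == (1, 0)
        bad = SequenceRecord(
            "t", "dna", "C" + core + "TTTT" + reverse_complement(rev))
        assert insilico_pcr(bad, pair).functional_call == "no_amplicon"

    def test_overlapping_forward_hits_raise_ambiguity(self):
        rng = np.random.default_rng(8)
        fwd = random_dna(rng, 20)
        rev = random_dna(rng, 20)
        template = SequenceRecord(
            "t", "dna",
            fwd + random_dna(rng, 30) + fwd + random_dna(rng, 30)
            + reverse_complement(rev))
        with pytest.raises(AmbiguousPrimingError, match="overlapping"):
            insilico_pcr(template, PrimerPair("p", fwd, rev))

    def test_zero_mismatch_hits_subset_of_tolerant_hits(self):
        rng = np.random.default_rng(9)
        fwd, rev = random_dna(rng, 20), random_dna(rng, 20)
        mutated = "T" + fwd[1:] if fwd[0] != "T" else "A" + fwd[1:]
        template = SequenceRecord(
            "t", "dna", mutated + random_dna(rng, 50) + reverse_complement(rev))
        strict = insilico_pcr(template, PrimerPair("p", fwd, rev),
                              max_mismatches=0)
        loose = insilico_pcr(template, PrimerPair("p", fwd, rev),
                             max_mismatches=1)
        assert strict.functional_call == "no_amplicon"
        assert loose.amplicon_length == 20 + 50 + 20


class TestSpliceVariantScan:
    def test_amplicon_length_conservation(self, fixture):
        """full - skip == sum of skipped exon lengths, for every skip set."""
        results = splice_variant_scan(
            fixture.model, fixture.genome, fixture.primers,
            triad_codon_positions=fixture.triad_genomic_positions)
        by_skip = {r.skipped_exons: r for r in results}
        full = by_skip[frozenset()].amplicon_length
        exon_len = {k: e - s + 1
                    for k, (s, e) in enumerate(fixture.model.exons, 1)}
        for skipped, r in by_skip.items():
            if r.amplicon_length is None:
                continue
            assert full - r.amplicon_length == \
                sum(exon_len[k] for k in skipped)
            assert r.amplicon_length == fixture.amplicon_lengths[skipped]

    def test_triad_bearing_skips_called_disrupted(self, fixture):
        results = splice_variant_scan(
            fixture.model, fixture.genome, fixture.primers,
            triad_codon_positions=fixture.triad_genomic_positions)
        for r in results:
            if fixture.triad_exon in r.skipped_exons:
                assert r.functional_call == "triad_disrupted"

    def test_frame_preserving_non_triad_skip_is_intact(self, fixture):
        # exon length 201 is a multiple of 3; skipping exon 2 keeps frame
        results = {r.skipped_exons: r for r in splice_variant_scan(
            fixture.model, fixture.genome, fixture.primers,
            triad_codon_positions=fixture.triad_genomic_positions)}
        assert results[frozenset({2})].functional_call == "intact"

    def test_frameshift_detected(self):
        # full CDS 801 bp is in frame; dropping the 200 bp exon 2 breaks it,
        # dropping exons 2+3 (399 bp) restores it
        fx = make_gene_fixture(n_exons=4, exon_lengths=[201, 200, 199, 201],
                               seed=18)
        results = {r.skipped_exons: r for r in splice_variant_scan(
            fx.model, fx.genome, fx.primers)}
        assert results[frozenset()].functional_call == "intact"
        assert results[frozenset({2})].functional_call == "frameshifted"
        assert results[frozenset({2, 3})].functional_call == "intact"

    def test_skip_removing_primer_site_gives_no_amplicon(self):
        fx = make_gene_fixture(n_exons=4, exon_lengths=201, seed=19)
        results = splice_variant_scan(fx.model, fx.genome, fx.primers,
                                      skip_sets=[{1, 2}])
        assert results[0].functional_call == "no_amplicon"

    def test_single_exon_gene_rejected(self):
        genome = SequenceRecord("g", "dna", "ACGT" * 30)
        model = GeneModel("m", "g", "+", ((1, 60),))
        with pytest.raises(PcrError, match=">=2 exons"):
            splice_variant_scan(model, genome,
                                PrimerPair("p", "ACGTACGTAC", "ACGTACGTAC"))

    def test_default_skip_sets_are_contiguous_internal(self):
        sets = contiguous_internal_skip_sets(5)
        assert frozenset() in sets
        assert frozenset({2, 3, 4}) in sets
        assert frozenset({1}) not in sets
        assert frozenset({5}) not in sets
        assert frozenset({2, 4}) not in sets
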