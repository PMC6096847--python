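"""In-silico PCR on transcripts assembled from gene models, with
exon-skipping enumeration and functional-impact calls.

Transcripts are built by concatenating retained exon sequences in
transcript (strand) order; exon ordinals follow that order, so "exon 4" of
a minus-strand gene is the fourth exon of the mRNA, not the fourth genomic
block.  Amplicons span the first forward-primer hit to the last compatible
reverse-primer hit (the longest product, matching gel interpretation of
full-length bands), both primers included.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .io_core import (
    GeneModel, GranzymeKitError, IUPAC_DNA, PrimerPair, SequenceRecord,
)


class PcrError(GranzymeKitError):
    """Invalid in-silico PCR request."""


class AmbiguousPrimingError(PcrError):
    """Multiple forward hits produce overlapping products."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Transcript assembly
# ---------------------------------------------------------------------------

def assemble_transcript(model: GeneModel, genome: SequenceRecord,
                        skipped: Iterable[int] = ()) -> SequenceRecord:
    """Concatenate retained exons into a transcript sequence.

    ``skipped`` holds 1-based exon ordinals in transcript order.  For
    minus-strand genes the result is the reverse complement of the retained
    genomic blocks, ordered 5'->3' along the mRNA.
    """
    if genome.alphabet != "dna":
        raise PcrError(f"{model.gene_id}: genome record must be dna")
    skipped = frozenset(int(k) for k in skipped)
    n = model.n_exons
    bad = [k for k in skipped if not 1 <= k <= n]
    if bad:
        raise PcrError(f"{model.gene_id}: invalid exon ordinals {sorted(bad)}")
    if len(skipped) == n:
        raise PcrError(f"{model.gene_id}: cannot skip all exons")
    parts = []
    for ordinal, (start, end) in enumerate(model.transcript_exons(), 1):
        if ordinal in skipped:
            continue
        block = genome.residues[start - 1:end]
        if len(block) != end - start + 1:
            raise PcrError(
                f"{model.gene_id}: exon ({start},{end}) outside genome "
                f"sequence of length {len(genome.residues)}"
            )
        parts.append(block if model.strand == "+" else reverse_complement(block))
    name = model.gene_id
    if skipped:
        name += "_skip" + "_".join(str(k) for k in sorted(skipped))
    return SequenceRecord(name, "dna", "".join(parts),
                          description=f"transcript of {model.gene_id}",
                          role="transcript")


# ---------------------------------------------------------------------------
# Primer matching
# ---------------------------------------------------------------------------

def _mismatches(primer: str, window: str) -> int:
    """Mismatch count; IUPAC codes match when their expansions intersect."""
    n = 0
    for p, t in zip(primer, window):
        ep = IUPAC_DNA.get(p, frozenset())
        et = IUPAC_DNA.get(t, frozenset())
        if not ep & et:
            n += 1
    return n


def _find_hits(template: str, primer: str, max_mismatches: int) -> list[tuple[int, int]]:
    """(1-based start, mismatches) for every placement within tolerance."""
    hits = []
    L = len(primer)
    for start in range(len(template) - L + 1):
        mm = _mismatches(primer, template[start:start + L])
        if mm <= max_mismatches:
            hits.append((start + 1, mm))
    return hits


# ---------------------------------------------------------------------------
# Amplicons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconResult:
    """One in-silico PCR outcome on one template."""

    primer_name: str
    template_id: str
    skipped_exons: frozenset[int]
    amplicon_length: int | None
    forward_hit: tuple[int, int] | None   # (1-based start, mismatches)
    reverse_hit: tuple[int, int] | None   # (1-based start of rc site, mismatches)
    functional_call: str

    def __post_init__(self) -> None:
        if (self.amplicon_length is None) != (self.functional_call == "no_amplicon"):
            raise PcrError("no_amplicon iff amplicon length absent")

    def summary_row(self) -> dict:
        return {
            "primer_name": self.primer_name,
            "template_id": self.template_id,
            "skipped_exons": ",".join(map(str, sorted(self.skipped_exons))) or "-",
            "amplicon_length": self.amplicon_length,
            "functional_call": self.functional_call,
        }


def insilico_pcr(template: SequenceRecord, primers: PrimerPair,
                 max_mismatches: int = 0,
                 skipped_exons: Iterable[int] = (),
                 functional_call: str | None = None,
                 mode: str = "longest") -> AmpliconResult:
    """Run one primer pair against one template.

    The forward primer is matched on the template 5'->3'; the reverse
    primer is matched as its reverse complement strictly downstream of the
    forward hit.  The product spans the first forward hit to the last
    compatible reverse hit (longest product), inclusive of both primers.
    ``mode="all"`` is handled by :func:`insilico_pcr_all`.  Multiple forward
    hits whose products overlap raise :class:`AmbiguousPrimingError`.
    """
    if template.alphabet != "dna":
        raise PcrError(f"{template.id}: PCR template must be dna")
    if mode != "longest":
        raise PcrError("insilico_pcr runs in 'longest' mode; "
                       "use insilico_pcr_all for every product")
    seq = template.residues
    fwd_hits = _find_hits(seq, primers.forward, max_mismatches)
    rc_rev = reverse_complement(primers.reverse)
    rev_hits = _find_hits(seq, rc_rev, max_mismatches)

    def product_for(fh: tuple[int, int]) -> tuple[int, tuple[int, int]] | None:
        compatible = [rh for rh in rev_hits
                      if rh[0] >= fh[0] + len(primers.forward)]
        if not compatible:
            return None
        rh = compatible[-1]
        length = rh[0] + len(rc_rev) - fh[0]
        return length, rh

    products = [(fh, product_for(fh)) for fh in fwd_hits]
    products = [(fh, p) for fh, p in products if p is not None]
    if len(products) > 1:
        spans = [(fh[0], fh[0] + p[0] - 1) for fh, p in products]
        overlapping = any(
            s1 <= e2 and s2 <= e1
            for (s1, e1), (s2, e2) in combinations(spans, 2)
        )
        if overlapping:
            raise AmbiguousPrimingError(
                f"{primers.name} on {template.id}: multiple forward hits with "
                f"overlapping products at starts "
                f"{[fh[0] for fh, _ in products]}"
            )
    skipped = frozenset(int(k) for k in skipped_exons)
    if not products:
        return AmpliconResult(primers.name, template.id, skipped,
                              None, None, None, "no_amplicon")
    fh, (length, rh) = products[0]
    call = functional_call or "intact"
    return AmpliconResult(primers.name, template.id, skipped,
                          length, fh, rh, call)


def insilico_pcr_all(template: SequenceRecord, primers: PrimerPair,
                     max_mismatches: int = 0) -> list[AmpliconResult]:
    """Every forward/reverse hit combination as a separate product."""
    seq = template.residues
    fwd_hits = _find_hits(seq, primers.forward, max_mismatches)
    rc_rev = reverse_complement(primers.reverse)
    rev_hits = _find_hits(seq, rc_rev, max_mismatches)
    out = []
    for fh in fwd_hits:
        for rh in rev_hits:
            if rh[0] >= fh[0] + len(primers.forward):
                length = rh[0] + len(rc_rev) - fh[0]
                out.append(AmpliconResult(
                    primers.name, template.id, frozenset(),
                    length, fh, rh, "intact"))
    return out


# ---------------------------------------------------------------------------
# Splice-variant scan
# ---------------------------------------------------------------------------

def contiguous_internal_skip_sets(n_exons: int) -> list[frozenset[int]]:
    """All contiguous subsets of internal exons (ordinals 2..n-1), plus the
    empty set (full-length transcript)."""
    sets: list[frozenset[int]] = [frozenset()]
    for a in range(2, n_exons):
        for b in range(a, n_exons):
            sets.append(frozenset(range(a, b + 1)))
    return sets


def _functional_call(model: GeneModel, skipped: frozenset[int],
                     triad_codon_positions: Sequence[int]) -> str:
    """Impact of a skip set: triad loss dominates, then frame, then intact."""
    tx_exons = model.transcript_exons()
    for pos in triad_codon_positions:
        for ordinal, (start, end) in enumerate(tx_exons, 1):
            if start <= pos <= end and ordinal in skipped:
                return "triad_disrupted"
    retained = sum(
        end - start + 1
        for ordinal, (start, end) in enumerate(tx_exons, 1)
        if ordinal not in skipped
    )
    if retained % 3 != 0:
        return "frameshifted"
    return "intact"


def splice_variant_scan(model: GeneModel, genome: SequenceRecord,
                        primers: PrimerPair,
                        triad_codon_positions: Sequence[int] = (),
                        skip_sets: Sequence[Iterable[int]] | None = None,
                        max_mismatches: int = 0) -> list[AmpliconResult]:
    """Enumerate exon-skipping variants and size/score their amplicons.

    ``triad_codon_positions`` are 1-based genomic coordinates of catalytic
    triad codon bases; a variant skipping an exon carrying any of them is
    called ``triad_disrupted``.  Variants whose retained coding length is
    not a multiple of 3 are ``frameshifted``; failed amplification is
    ``no_amplicon``; otherwise ``intact``.  Default skip sets are all
    contiguous internal-exon subsets (including the full-length transcript).
    """
    if model.n_exons < 2:
        raise PcrError(f"{model.gene_id}: splice scan requires >=2 exons")
    if skip_sets is None:
        skip_sets = contiguous_internal_skip_sets(model.n_exons)
    results = []
    for skipped in skip_sets:
        skipped = frozenset(int(k) for k in skipped)
        transcript = assemble_transcript(model, genome, skipped)
        result = insilico_pcr(transcript, primers, max_mismatches,
                              skipped_exons=skipped)
        if result.functional_call != "no_amplicon":
            call = _functional_call(model, skipped, triad_codon_positions)
            result = AmpliconResult(
                result.primer_name, result.template_id, skipped,
                result.amplicon_length, result.forward_hit,
                result.reverse_hit, call)
        results.append(result)
    return results
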