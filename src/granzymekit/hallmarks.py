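"""Hallmark-feature validation for granzyme-family serine proteases.

Given a mature protein carrying a canonical :class:`~granzymekit.align.NumberingMap`,
these checks validate the diagnostic architecture of the family:

* a signal-peptide cleavage site on the precursor, scored by a
  position-weight matrix over the window -13..+2 around the candidate site;
* the N-terminal consensus motifs IIGG (positions 1-4) and PHSRPYMA
  (positions 9-16);
* the catalytic triad (His57 / Asp102 / Ser195 by default, with
  configurable presets covering the alternative numberings in circulation);
* the three-to-four conserved disulfide cysteine pairs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import NumberingMap
from .io_core import GranzymeKitError, SequenceRecord, _data_path

# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

MOTIF_1_4 = "IIGG"
MOTIF_9_16 = "PHSRPYMA"

#: Canonical triad position presets.  ``standard`` is the chymotrypsinogen
#: scheme; the two alternatives cover numbering variants seen in the
#: literature for the same residues.
TRIAD_PRESETS: dict[str, dict[str, int]] = {
    "standard": {"His": 57, "Asp": 102, "Ser": 195},
    "alt-103": {"His": 57, "Asp": 103, "Ser": 195},
    "alt-45-95": {"His": 45, "Asp": 95, "Ser": 195},
}

TRIAD_RESIDUES = {"His": "H", "Asp": "D", "Ser": "S"}

#: Conserved disulfide pairs (canonical numbering).
DEFAULT_CYSTEINE_PAIRS: tuple[tuple[int, int], ...] = (
    (30, 46), (162, 180), (191, 221), (130, 201)
)

DEFAULT_CLEAVAGE_RANGE = (10, 40)
DEFAULT_MOTIF_MISMATCH_CEILING = 2
MIN_CYSTEINE_PAIRS = 3


class HallmarkError(GranzymeKitError):
    """Input unusable for a hallmark check (too short, bad window...)."""


# ---------------------------------------------------------------------------
# Signal-peptide cleavage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageModel:
    """Position-weight matrix over residues x window positions.

    ``positions`` are offsets relative to the cleavage site (negative =
    signal side, positive = mature side; -1 is the last signal residue).
    ``weights`` maps each of the 20 residues to one weight per position.
    """

    positions: tuple[int, ...]
    weights: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        w = {a: tuple(v) for a, v in self.weights.items()}
        object.__setattr__(self, "weights", w)
        npos = len(self.positions)
        if len(w) < 20:
            raise HallmarkError("cleavage model must cover all 20 residues")
        for a, row in w.items():
            if len(row) != npos:
                raise HallmarkError(
                    f"cleavage model residue {a}: {len(row)} weights for "
                    f"{npos} positions"
                )

    def score_at(self, sequence: str, position: int) -> float:
        """Score cleavage after 1-based ``position`` of ``sequence``."""
        total = 0.0
        for col, off in enumerate(self.positions):
            # offsets are relative to the scissile bond: -1 is residue
            # `position`, +1 is residue position+1
            idx = position + off + 1 if off < 0 else position + off
            res = sequence[idx - 1]
            total += self.weights.get(res, (0.0,) * len(self.positions))[col]
        return total

    def window_span(self) -> tuple[int, int]:
        """(residues needed before the site, residues needed after)."""
        before = -min(p for p in self.positions if p < 0)
        after = max([p for p in self.positions if p > 0], default=0)
        return before, after

    def optimal_residues(self) -> dict[int, str]:
        """Per-position argmax residue (ties: alphabetical)."""
        out = {}
        for col, pos in enumerate(self.positions):
            out[pos] = max(sorted(self.weights), key=lambda a: self.weights[a][col])
        return out


def load_cleavage_model() -> CleavageModel:
    """Packaged synthetic signal-peptide cleavage weight matrix.

    The matrix is constructed, not transcribed from a published count table:
    columns encode the standard qualitative signal-peptide chemistry (a
    hydrophobic h-region at -13..-6, turn residues at -5, small residues
    required at -3 and -1).  See ``data/cleavage_matrix_synthetic.json``.
    """
    with open(_data_path("cleavage_matrix_synthetic.json")) as fh:
        raw = json.load(fh)
    return CleavageModel(tuple(raw["positions"]),
                         {a: tuple(v) for a, v in raw["weights"].items()})


def rule_31_score(sequence: str, position: int) -> float:
    """Fallback (-3, -1) small-residue cleavage scorer.

    Scores 1 for an allowed small residue at -3 (A/V/C/S/T/G) and at -1
    (A/G/S), 0 otherwise; maximum 2.
    """
    if position < 3:
        return 0.0
    m3, m1 = sequence[position - 3], sequence[position - 1]
    return float(m3 in "AVCSTG") + float(m1 in "AGS")


def predict_cleavage(precursor: SequenceRecord,
                     model: CleavageModel | None = None,
                     search_range: tuple[int, int] = DEFAULT_CLEAVAGE_RANGE,
                     scorer: str = "matrix") -> tuple[int, float]:
    """Predict the signal-peptide cleavage position of a precursor.

    Every candidate position in ``search_range`` (cleavage occurs after the
    returned 1-based position) whose scoring window fits the sequence is
    scored; the argmax is returned, ties resolving to the smallest position.
    ``scorer="rule31"`` selects the simple (-3,-1) rule instead of the
    weight matrix.
    """
    seq = precursor.residues
    model = model or load_cleavage_model()
    before, after = model.window_span()
    lo = max(search_range[0], before)
    hi = min(search_range[1], len(seq) - after)
    if lo > hi:
        raise HallmarkError(
            f"{precursor.id}: sequence of length {len(seq)} leaves no valid "
            f"cleavage window in range {search_range}"
        )
    best_pos, best_score = None, None
    for pos in range(lo, hi + 1):
        s = (model.score_at(seq, pos) if scorer == "matrix"
             else rule_31_score(seq, pos))
        if best_score is None or s > best_score:
            best_pos, best_score = pos, s
    return best_pos, best_score


# ---------------------------------------------------------------------------
# Motifs, triad, cysteines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifResult:
    """Per-position match flags for one N-terminal consensus motif."""

    motif: str
    start: int  # canonical position of the first motif residue
    observed: str
    flags: tuple[bool, ...]

    @property
    def mismatches(self) -> list[tuple[int, str, str]]:
        return [
            (self.start + k, self.motif[k], self.observed[k])
            for k, ok in enumerate(self.flags) if not ok
        ]

    @property
    def n_pass(self) -> int:
        return sum(self.flags)


def _residue_at(mature: str, nmap: NumberingMap | None, canonical: int) -> str | None:
    if nmap is None:
        return mature[canonical - 1] if canonical <= len(mature) else None
    return nmap.residue_at(mature, canonical)


def check_motifs(mature: SequenceRecord,
                 nmap: NumberingMap | None = None) -> tuple[MotifResult, MotifResult]:
    """Compare positions 1-4 and 9-16 of the mature chain to IIGG / PHSRPYMA.

    Precondition: the mature sequence begins at canonical position 1, so
    motif residues are read directly at positions 1-16.  The numbering map
    is deliberately *not* used for the lookup: the N-terminal consensus is
    what defines the mature start, and this very region diverges from the
    numbering reference in family members, making alignment-transferred
    numbers circular exactly here.  Comparison is exact per position.
    """
    if len(mature.residues) < 16:
        raise HallmarkError(
            f"{mature.id}: mature sequence of length {len(mature.residues)} "
            "is shorter than the motif region (16)"
        )
    results = []
    for motif, start in ((MOTIF_1_4, 1), (MOTIF_9_16, 9)):
        observed = mature.residues[start - 1:start - 1 + len(motif)]
        flags = tuple(o == e for o, e in zip(observed, motif))
        results.append(MotifResult(motif, start, observed, flags))
    return results[0], results[1]


@dataclass(frozen=True)
class TriadSite:
    """One catalytic-triad member check."""

    name: str
    canonical: int
    expected: str
    observed: str | None
    passed: bool
    reason: str = ""


def check_triad(mature: SequenceRecord, nmap: NumberingMap,
                positions: Mapping[str, int] | str = "standard") -> dict[str, TriadSite]:
    """Check His/Asp/Ser of the catalytic triad at canonical positions.

    ``positions`` is a preset name from :data:`TRIAD_PRESETS` or an explicit
    mapping {"His": n, "Asp": n, "Ser": n}.  A canonical position absent
    from the numbering map is reported as failed with reason ``"deleted"``
    (never an exception): exon-skipping variants legitimately lose triad
    codons.
    """
    if isinstance(positions, str):
        try:
            positions = TRIAD_PRESETS[positions]
        except KeyError:
            raise HallmarkError(
                f"unknown triad preset {positions!r}; "
                f"available: {sorted(TRIAD_PRESETS)}"
            ) from None
    out: dict[str, TriadSite] = {}
    for name, canonical in positions.items():
        expected = TRIAD_RESIDUES[name]
        observed = nmap.residue_at(mature.residues, canonical)
        if observed is None:
            out[name] = TriadSite(name, canonical, expected, None, False, "deleted")
        else:
            out[name] = TriadSite(
                name, canonical, expected, observed, observed == expected,
                "" if observed == expected else "substituted",
            )
    return out


@dataclass(frozen=True)
class CysteinePair:
    pos_a: int
    pos_b: int
    res_a: str | None
    res_b: str | None
    present: bool


def check_cysteines(mature: SequenceRecord, nmap: NumberingMap,
                    pairs: Sequence[tuple[int, int]] = DEFAULT_CYSTEINE_PAIRS
                    ) -> list[CysteinePair]:
    """Check the conserved disulfide cysteine pairs.

    A pair is present iff both canonical positions are assigned and both
    carry a cysteine.  Family members typically show 3 or 4 of the 4 pairs.
    """
    out = []
    for a, b in pairs:
        ra = nmap.residue_at(mature.residues, a)
        rb = nmap.residue_at(mature.residues, b)
        out.append(CysteinePair(a, b, ra, rb, ra == "C" and rb == "C"))
    return out


# ---------------------------------------------------------------------------
# Consolidated report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HallmarkReport:
    """All hallmark checks for one query.

    ``overall_pass`` is true iff the full triad passes, at least
    ``MIN_CYSTEINE_PAIRS`` cysteine pairs are present and the total motif
    mismatch count does not exceed the configured ceiling.
    """

    query_id: str
    cleavage_site: tuple[int, float] | None
    motif_1_4: MotifResult
    motif_9_16: MotifResult
    triad: dict[str, TriadSite]
    cysteine_pairs: list[CysteinePair]
    overall_pass: bool

    def summary_row(self) -> dict:
        """Flat dict for TSV/JSON reporting."""
        return {
            "query_id": self.query_id,
            "cleavage_position": self.cleavage_site[0] if self.cleavage_site else None,
            "cleavage_score": self.cleavage_site[1] if self.cleavage_site else None,
            "motif_1_4_pass": self.motif_1_4.n_pass,
            "motif_9_16_pass": self.motif_9_16.n_pass,
            "triad_pass": all(t.passed for t in self.triad.values()),
            "cysteine_pairs_present": sum(p.present for p in self.cysteine_pairs),
            "overall_pass": self.overall_pass,
        }


def evaluate_hallmarks(mature: SequenceRecord, nmap: NumberingMap,
                       precursor: SequenceRecord | None = None,
                       cleavage_model: CleavageModel | None = None,
                       triad_positions: Mapping[str, int] | str = "standard",
                       cysteine_pairs: Sequence[tuple[int, int]] = DEFAULT_CYSTEINE_PAIRS,
                       motif_mismatch_ceiling: int = DEFAULT_MOTIF_MISMATCH_CEILING,
                       min_cysteine_pairs: int = MIN_CYSTEINE_PAIRS) -> HallmarkReport:
    """Run every hallmark check and consolidate into a :class:`HallmarkReport`."""
    cleavage = None
    if precursor is not None:
        cleavage = predict_cleavage(precursor, cleavage_model)
    m14, m916 = check_motifs(mature, nmap)
    triad = check_triad(mature, nmap, triad_positions)
    cys = check_cysteines(mature, nmap, cysteine_pairs)
    mismatches = (len(m14.flags) - m14.n_pass) + (len(m916.flags) - m916.n_pass)
    overall = (
        all(t.passed for t in triad.values())
        and sum(p.present for p in cys) >= min_cysteine_pairs
        and mismatches <= motif_mismatch_ceiling
    )
    return HallmarkReport(mature.id, cleavage, m14, m916, triad, cys, overall)
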