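"""Global alignment, percent identity and canonical-numbering transfer.

Pairwise alignment is Needleman-Wunsch with affine gaps (Gotoh), protein
scoring by BLOSUM62 and nucleotide scoring by match/mismatch, with the
ClustalW-like defaults gap open 10 / extend 0.5.  Multiple alignment is
progressive: a neighbour-joining guide tree on pairwise p-distances, then
profile-profile merges in guide-tree order.

Canonical residue numbering for serine proteases is transferred from the
packaged bovine chymotrypsinogen A reference by pairwise alignment: every
query residue aligned to a reference residue inherits that residue's
canonical number; insertions relative to the reference stay unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np

from .io_core import GranzymeKitError, SequenceRecord, IUPAC_DNA

# ---------------------------------------------------------------------------
# Scoring parameters
# ---------------------------------------------------------------------------

DEFAULT_GAP_OPEN = 10.0     # cost of the first residue of a gap
DEFAULT_GAP_EXTEND = 0.5    # cost of each additional gap residue
DNA_MATCH = 5.0
DNA_MISMATCH = -4.0


class AlignmentError(GranzymeKitError):
    """Invalid alignment request (mixed alphabets, empty input, ...)."""


class LowCoverageError(AlignmentError):
    """Numbering transfer covered too little of the reference."""


@lru_cache(maxsize=None)
def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def _protein_score(a: str, b: str) -> float:
    return _blosum62().get((a, b), 0.0)


def _dna_score(a: str, b: str) -> float:
    if a == "N" or b == "N":
        return 0.0
    if a == b:
        return DNA_MATCH
    ea, eb = IUPAC_DNA.get(a), IUPAC_DNA.get(b)
    if ea and eb and (ea & eb):
        return 1.0  # compatible ambiguity codes: weak positive
    return DNA_MISMATCH


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for global alignment.

    ``matrix`` may be ``None`` (alphabet default: BLOSUM62 for protein,
    +5/-4 for dna) or a mapping ``(res_a, res_b) -> score``.
    ``empty_policy`` controls empty-sequence input: ``"error"`` (default)
    rejects it, ``"allow"`` produces an all-gap row.
    """

    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    matrix: Mapping[tuple[str, str], float] | None = None
    empty_policy: str = "error"

    def scorer(self, alphabet: str) -> Callable[[str, str], float]:
        if self.matrix is not None:
            m = self.matrix
            return lambda a, b: float(m.get((a, b), m.get((b, a), 0.0)))
        return _protein_score if alphabet == "protein" else _dna_score


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A set of equal-length gapped rows plus the alignment score."""

    rows: tuple[tuple[str, str], ...]
    score: float = 0.0

    def __post_init__(self) -> None:
        rows = tuple((i, s.upper()) for i, s in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise AlignmentError("alignment requires at least one row")
        ncols = len(rows[0][1])
        if any(len(s) != ncols for _, s in rows):
            raise AlignmentError("alignment rows differ in length")
        ids = [i for i, _ in rows]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate row ids in alignment")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    def row(self, row_id: str) -> str:
        for i, s in self.rows:
            if i == row_id:
                return s
        raise KeyError(row_id)

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def to_fasta(self, path) -> None:
        from .io_core import FASTA_LINE_WIDTH

        with open(path, "w") as fh:
            for rid, s in self.rows:
                fh.write(f">{rid}\n")
                for k in range(0, len(s), FASTA_LINE_WIDTH):
                    fh.write(s[k:k + FASTA_LINE_WIDTH] + "\n")


# ---------------------------------------------------------------------------
# Gotoh core
# ---------------------------------------------------------------------------

_NEG = -1e30


def _gotoh(n: int, m: int, score: Callable[[int, int], float],
           go: float, ge: float) -> tuple[float, list[str]]:
    """Affine-gap global alignment over abstract columns.

    ``score(i, j)`` scores pairing item i of A (1-based) with item j of B.
    Returns the optimal score and the operation list ('M' pair, 'X' consume
    A against a gap, 'Y' consume B against a gap).  Tie-break preference at
    every choice point: M > X > Y (match, then gap placed in B, then gap
    placed in A), giving a deterministic trace-back.
    """
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    # pointer values encode predecessor state: 0=M, 1=X, 2=Y
    Mp = np.zeros((n + 1, m + 1), dtype=np.int8)
    Xp = np.zeros((n + 1, m + 1), dtype=np.int8)
    Yp = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
        Xp[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge
        Yp[0, j] = 0 if j == 1 else 2

    def _best(m_val, x_val, y_val):
        # preference M > X > Y on exact ties
        if m_val >= x_val and m_val >= y_val:
            return m_val, 0
        if x_val >= y_val:
            return x_val, 1
        return y_val, 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(i, j)
            best, ptr = _best(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best + s
            Mp[i, j] = ptr
            best, ptr = _best(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            X[i, j] = best
            Xp[i, j] = ptr
            best, ptr = _best(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            Y[i, j] = best
            Yp[i, j] = ptr

    final, state = _best(M[n, m], X[n, m], Y[n, m])
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops.append("M")
            state = Mp[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("X")
            state = Xp[i, j]
            i -= 1
        else:
            ops.append("Y")
            state = Yp[i, j]
            j -= 1
    ops.reverse()
    return float(final), ops


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

def global_align(a: SequenceRecord, b: SequenceRecord,
                 params: AlignParams | None = None) -> Alignment:
    """Optimal global alignment of two records under affine-gap scoring.

    Both records must share an alphabet.  Empty sequences are rejected by
    ``SequenceRecord`` itself; ``params.empty_policy`` exists for callers
    constructing degenerate alignments from raw strings via
    :func:`global_align_strings`.
    """
    if a.alphabet != b.alphabet:
        raise AlignmentError(
            f"mixed alphabets: {a.id} is {a.alphabet}, {b.id} is {b.alphabet}"
        )
    params = params or AlignParams()
    return global_align_strings(a.id, a.residues, b.id, b.residues,
                                a.alphabet, params)


def global_align_strings(id_a: str, seq_a: str, id_b: str, seq_b: str,
                         alphabet: str, params: AlignParams | None = None) -> Alignment:
    """String-level entry point for :func:`global_align`."""
    params = params or AlignParams()
    if not seq_a or not seq_b:
        if params.empty_policy != "allow":
            raise AlignmentError(
                f"empty sequence in alignment of {id_a!r} vs {id_b!r}"
            )
        n = max(len(seq_a), len(seq_b), 0)
        go, ge = params.gap_open, params.gap_extend
        cost = 0.0 if n == 0 else -(go + (n - 1) * ge)
        return Alignment(
            ((id_a, seq_a or "-" * len(seq_b)), (id_b, seq_b or "-" * len(seq_a))),
            score=cost,
        )
    sc = params.scorer(alphabet)
    score = lambda i, j: sc(seq_a[i - 1], seq_b[j - 1])
    total, ops = _gotoh(len(seq_a), len(seq_b), score,
                        params.gap_open, params.gap_extend)
    ga, gb = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            ga.append(seq_a[i]); gb.append(seq_b[j]); i += 1; j += 1
        elif op == "X":
            ga.append(seq_a[i]); gb.append("-"); i += 1
        else:
            ga.append("-"); gb.append(seq_b[j]); j += 1
    return Alignment(((id_a, "".join(ga)), (id_b, "".join(gb))), score=total)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile_align(prof_a: list[tuple[str, str]], prof_b: list[tuple[str, str]],
                   scorer: Callable[[str, str], float],
                   go: float, ge: float) -> tuple[float, list[tuple[str, str]]]:
    """Merge two profiles with Gotoh; columns scored by average pair score."""
    cols_a = list(zip(*[s for _, s in prof_a]))
    cols_b = list(zip(*[s for _, s in prof_b]))
    na, nb = len(cols_a), len(cols_b)

    def col_score(i: int, j: int) -> float:
        total = 0.0
        pairs = 0
        for ra in cols_a[i - 1]:
            for rb in cols_b[j - 1]:
                pairs += 1
                if ra != "-" and rb != "-":
                    total += scorer(ra, rb)
        return total / pairs

    total, ops = _gotoh(na, nb, col_score, go, ge)
    out_a = ["" for _ in prof_a]
    out_b = ["" for _ in prof_b]
    i = j = 0
    for op in ops:
        if op == "M":
            for k, c in enumerate(cols_a[i]):
                out_a[k] += c
            for k, c in enumerate(cols_b[j]):
                out_b[k] += c
            i += 1; j += 1
        elif op == "X":
            for k, c in enumerate(cols_a[i]):
                out_a[k] += c
            for k in range(len(out_b)):
                out_b[k] += "-"
            i += 1
        else:
            for k in range(len(out_a)):
                out_a[k] += "-"
            for k, c in enumerate(cols_b[j]):
                out_b[k] += c
            j += 1
    merged = [(rid, out_a[k]) for k, (rid, _) in enumerate(prof_a)]
    merged += [(rid, out_b[k]) for k, (rid, _) in enumerate(prof_b)]
    return total, merged


def _pairwise_p_distance(a: SequenceRecord, b: SequenceRecord,
                         params: AlignParams) -> float:
    aln = global_align(a, b, params)
    ident = percent_identity(aln, a.id, b.id, mode="aligned_columns")
    return 1.0 - ident / 100.0


def progressive_msa(records: Sequence[SequenceRecord],
                    params: AlignParams | None = None) -> Alignment:
    """Progressive multiple alignment.

    Guide tree: neighbour joining on pairwise p-distances (ids sorted
    lexicographically before tree building so ties break deterministically);
    profiles are merged bottom-up in guide-tree order.  With two records the
    result equals :func:`global_align`.  Output rows follow input order.
    """
    params = params or AlignParams()
    if len(records) < 2:
        raise AlignmentError("progressive_msa requires at least 2 records")
    alphabets = {r.alphabet for r in records}
    if len(alphabets) != 1:
        raise AlignmentError("progressive_msa requires a single alphabet")
    if len(records) == 2:
        return global_align(records[0], records[1], params)

    from .phylo import DistanceMatrix, neighbour_joining

    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise AlignmentError("duplicate record ids")
    labels = sorted(by_id)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_p_distance(
                by_id[labels[i]], by_id[labels[j]], params
            )
    tree = neighbour_joining(DistanceMatrix(tuple(labels), d, model="p_distance",
                                            sites_used=0))
    scorer = params.scorer(records[0].alphabet)

    total_score = 0.0

    def build(node) -> list[tuple[str, str]]:
        nonlocal total_score
        if node.is_leaf():
            return [(node.label, by_id[node.label].residues)]
        profs = [build(child) for child, _ in node.children]
        merged = profs[0]
        for prof in profs[1:]:
            sc, merged = _profile_align(merged, prof, scorer,
                                        params.gap_open, params.gap_extend)
            total_score += sc
        return merged

    merged = build(tree.root)
    order = {r.id: k for k, r in enumerate(records)}
    merged.sort(key=lambda row: order[row[0]])
    return Alignment(tuple(merged), score=total_score)


# ---------------------------------------------------------------------------
# Percent identity / similarity
# ---------------------------------------------------------------------------

def _counted_columns(ra: str, rb: str, mode: str) -> list[int]:
    ncols = len(ra)
    if mode == "shorter_seq":
        return list(range(ncols))
    # aligned_columns: drop terminal overhangs and columns gapped in both rows
    both = [k for k in range(ncols) if ra[k] != "-" and rb[k] != "-"]
    if not both:
        return []
    lo, hi = both[0], both[-1]
    return [k for k in range(lo, hi + 1) if not (ra[k] == "-" and rb[k] == "-")]


def percent_identity(aln: Alignment, i: str, j: str,
                     mode: str = "aligned_columns",
                     metric: str = "identity",
                     params: AlignParams | None = None) -> float:
    """Percent identity (or similarity) between two rows of an alignment.

    ``aligned_columns`` excludes terminal overhangs and columns gapped in
    both rows from the denominator; ``shorter_seq`` divides by the shorter
    ungapped sequence length.  ``metric="similarity"`` counts residue pairs
    with a positive substitution-matrix score instead of exact matches.
    """
    if mode not in ("aligned_columns", "shorter_seq"):
        raise ValueError(f"unknown mode {mode!r}")
    if metric not in ("identity", "similarity"):
        raise ValueError(f"unknown metric {metric!r}")
    ra, rb = aln.row(i), aln.row(j)
    cols = _counted_columns(ra, rb, mode)
    if mode == "shorter_seq":
        denom = min(len(ra.replace("-", "")), len(rb.replace("-", "")))
    else:
        denom = len(cols)
    if denom == 0:
        raise AlignmentError(f"percent_identity: zero denominator for {i} vs {j}")
    if metric == "identity":
        hits = sum(1 for k in cols if ra[k] == rb[k] and ra[k] != "-")
    else:
        sc = (params or AlignParams()).scorer("protein")
        hits = sum(
            1 for k in cols
            if ra[k] != "-" and rb[k] != "-" and sc(ra[k], rb[k]) > 0
        )
    return 100.0 * hits / denom


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent identity and similarity matrices over labelled rows."""

    labels: tuple[str, ...]
    identity: np.ndarray
    similarity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("identity", "similarity"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise AlignmentError(f"{name} matrix shape {m.shape} != ({n},{n})")
            if not np.allclose(m, m.T):
                raise AlignmentError(f"{name} matrix not symmetric")
            if not np.allclose(np.diag(m), 100.0):
                raise AlignmentError(f"{name} diagonal must be 100")
            if m.min() < -1e-9 or m.max() > 100 + 1e-9:
                raise AlignmentError(f"{name} entries outside [0, 100]")

    def get(self, a: str, b: str, which: str = "identity") -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(getattr(self, which)[i, j])


def build_identity_matrix(records: Sequence[SequenceRecord],
                          params: AlignParams | None = None,
                          mode: str = "aligned_columns") -> IdentityMatrix:
    """All-against-all percent identity/similarity from pairwise alignments."""
    params = params or AlignParams()
    n = len(records)
    if n < 2:
        raise AlignmentError("identity matrix requires >=2 records")
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], params)
            ident[i, j] = ident[j, i] = percent_identity(
                aln, records[i].id, records[j].id, mode=mode)
            simil[i, j] = simil[j, i] = percent_identity(
                aln, records[i].id, records[j].id, mode=mode,
                metric="similarity", params=params)
    return IdentityMatrix(tuple(r.id for r in records), ident, simil)


# ---------------------------------------------------------------------------
# Canonical numbering transfer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumberingMap:
    """Canonical-number assignment for a query protein.

    ``assignments`` maps 1-based ungapped query residue indices to canonical
    (chymotrypsinogen-scheme) numbers.  Query residues aligned to reference
    gaps are absent from the map.  Assignments are strictly increasing along
    the query and each canonical number is used at most once, both guaranteed
    by alignment-column monotonicity and validated here.
    """

    query_id: str
    assignments: Mapping[int, int]

    def __post_init__(self) -> None:
        items = sorted(self.assignments.items())
        object.__setattr__(self, "assignments", dict(items))
        nums = [v for _, v in items]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise AlignmentError(
                f"{self.query_id}: canonical numbers not strictly increasing"
            )

    def inverse(self) -> dict[int, int]:
        """Canonical number -> query residue index."""
        return {v: k for k, v in self.assignments.items()}

    def residue_at(self, sequence: str | SequenceRecord, canonical: int) -> str | None:
        """Query residue carrying a canonical number, or None if unassigned."""
        seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
        qpos = self.inverse().get(canonical)
        return None if qpos is None else seq[qpos - 1]


def build_numbering_map(query: SequenceRecord, reference: SequenceRecord,
                        reference_numbers: Sequence[int],
                        params: AlignParams | None = None,
                        min_coverage: float = 0.5,
                        strict: bool = True) -> NumberingMap:
    """Transfer canonical residue numbers from a reference onto a query.

    The query is globally aligned to the reference; each query residue paired
    with a reference residue inherits that residue's entry from
    ``reference_numbers``.  If fewer than ``min_coverage`` of the reference
    residues are aligned to query residues, a :class:`LowCoverageError` is
    raised (or a warning issued when ``strict=False``).
    """
    if len(reference_numbers) != len(reference.residues):
        raise AlignmentError(
            "reference_numbers must have one entry per reference residue"
        )
    if query.alphabet != "protein" or reference.alphabet != "protein":
        raise AlignmentError("numbering transfer requires protein records")
    # distinct internal row ids allow numbering a reference against itself
    aln = global_align_strings("__query__", query.residues,
                               "__reference__", reference.residues,
                               "protein", params)
    ra, rb = aln.row("__query__"), aln.row("__reference__")
    assignments: dict[int, int] = {}
    qpos = rpos = 0
    covered = 0
    for ca, cb in zip(ra, rb):
        if ca != "-":
            qpos += 1
        if cb != "-":
            rpos += 1
        if ca != "-" and cb != "-":
            assignments[qpos] = int(reference_numbers[rpos - 1])
            covered += 1
    coverage = covered / len(reference.residues)
    if coverage < min_coverage:
        msg = (f"{query.id}: numbering transfer covers only "
               f"{coverage:.1%} of reference {reference.id} "
               f"(floor {min_coverage:.0%})")
        if strict:
            raise LowCoverageError(msg)
        warnings.warn(msg, stacklevel=2)
    return NumberingMap(query.id, assignments)
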