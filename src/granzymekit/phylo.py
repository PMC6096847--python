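"""Distance-based phylogenetics: TN93 composite-likelihood distances,
neighbour joining, bootstrap supports and group-monophyly checks.

The distance model follows the composite-likelihood approach used by
distance phylogenetics software: a single set of TN93 parameters (base
frequencies plus the two transition/transversion rate ratios) is estimated
by maximising the likelihood pooled over all sequence pairs, and each
pairwise distance is then the maximum-likelihood branch length under those
shared parameters.  A per-pair closed-form TN93 mode and the plain
p-distance are provided for cross-checking.

Alignment columns containing gaps or ambiguity codes in any row are removed
before distance computation (complete deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize

from .align import Alignment
from .io_core import GranzymeKitError

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Upper bracket for per-pair distance solving, substitutions/site.
MAX_DISTANCE = 20.0


class PhyloError(GranzymeKitError):
    """Invalid phylogenetic input."""


class SaturationError(PhyloError):
    """A sequence pair is too diverged for the distance formula."""


# ---------------------------------------------------------------------------
# Distance matrix container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise evolutionary distances in substitutions/site."""

    labels: tuple[str, ...]
    d: np.ndarray
    model: str
    sites_used: int
    meta: Mapping | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (n, n):
            raise PhyloError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise PhyloError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(d)) or d.min() < -1e-12:
            raise PhyloError("distances must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# Complete deletion
# ---------------------------------------------------------------------------

def complete_deletion(aln: Alignment) -> Alignment:
    """Remove every column containing a gap or ambiguity code in any row."""
    rows = [s for _, s in aln.rows]
    ncols = aln.ncols
    keep = [
        k for k in range(ncols)
        if all(r[k] in _BASES for r in rows)
    ]
    if not keep:
        raise PhyloError("complete deletion removed every column")
    new_rows = tuple(
        (rid, "".join(s[k] for k in keep)) for rid, s in aln.rows
    )
    return Alignment(new_rows, score=0.0)


# ---------------------------------------------------------------------------
# TN93 model machinery
# ---------------------------------------------------------------------------

class TN93Params:
    """TN93 substitution model with a fixed rate normalisation of 1.

    ``freqs`` are equilibrium base frequencies in ACGT order; ``k1`` and
    ``k2`` are the purine (A<->G) and pyrimidine (C<->T) transition rates
    relative to the transversion rate.
    """

    def __init__(self, freqs: Sequence[float], k1: float, k2: float):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-8 or freqs.min() <= 0:
            raise PhyloError("freqs must be 4 positive values summing to 1")
        if k1 <= 0 or k2 <= 0:
            raise PhyloError("rate ratios must be positive")
        self.freqs = freqs
        self.k1 = float(k1)
        self.k2 = float(k2)
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                pair = {i, j}
                if pair == {_BASE_INDEX["A"], _BASE_INDEX["G"]}:
                    rate = k1
                elif pair == {_BASE_INDEX["C"], _BASE_INDEX["T"]}:
                    rate = k2
                else:
                    rate = 1.0
                Q[i, j] = rate * freqs[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(freqs, np.diag(Q)))  # mean substitution rate
        self.Q = Q / mu
        evals, evecs = np.linalg.eig(self.Q)
        self._evals = np.real(evals)
        self._evecs = np.real(evecs)
        self._inv = np.linalg.inv(self._evecs)

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d) = exp(Q d), row-stochastic."""
        P = self._evecs @ np.diag(np.exp(self._evals * d)) @ self._inv
        return np.clip(P, 1e-300, None)


def _pair_counts(sa: str, sb: str) -> np.ndarray:
    """4x4 substitution count matrix for an aligned ACGT-only pair."""
    ia = np.frombuffer(sa.encode(), dtype=np.uint8)
    ib = np.frombuffer(sb.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (lut[ia], lut[ib]), 1)
    return counts


def _pair_loglik(counts: np.ndarray, params: TN93Params, d: float) -> float:
    P = params.transition_matrix(d)
    return float(np.sum(counts * np.log(params.freqs[:, None] * P)))


def _pair_score(counts: np.ndarray, params: TN93Params, d: float) -> float:
    """d/dd of the pair log-likelihood (uses P' = Q P)."""
    P = params.transition_matrix(d)
    dP = params.Q @ P
    return float(np.sum(counts * dP / P))


def _solve_pair_distance(counts: np.ndarray, params: TN93Params,
                         pair_name: str = "") -> float:
    off = counts.sum() - np.trace(counts)
    if off == 0:
        return 0.0
    lo, hi = 1e-9, MAX_DISTANCE
    if _pair_score(counts, params, lo) <= 0:
        return 0.0
    if _pair_score(counts, params, hi) >= 0:
        raise SaturationError(
            f"pair {pair_name or '?'} is saturated: likelihood increases "
            f"beyond {MAX_DISTANCE} substitutions/site"
        )
    return float(brentq(lambda d: _pair_score(counts, params, d),
                        lo, hi, xtol=1e-14, rtol=8.9e-16))


def estimate_base_frequencies(aln: Alignment) -> np.ndarray:
    """Pooled ACGT frequencies over all rows of a gap-free alignment."""
    counts = np.zeros(4)
    for _, s in aln.rows:
        for b, i in _BASE_INDEX.items():
            counts[i] += s.count(b)
    if counts.sum() == 0:
        raise PhyloError("no ACGT characters in alignment")
    counts = np.maximum(counts, 1e-6)
    return counts / counts.sum()


def _all_pair_counts(aln: Alignment) -> dict[tuple[str, str], np.ndarray]:
    out = {}
    for i in range(len(aln.rows)):
        for j in range(i + 1, len(aln.rows)):
            (ida, sa), (idb, sb) = aln.rows[i], aln.rows[j]
            out[(ida, idb)] = _pair_counts(sa, sb)
    return out


def estimate_shared_tn93(aln: Alignment,
                         freqs: np.ndarray | None = None) -> TN93Params:
    """Estimate shared TN93 rate ratios by pooled (composite) likelihood.

    The objective is the sum over all sequence pairs of the pair
    log-likelihood profiled over its own distance; ratios are optimised on a
    log scale with Nelder-Mead.
    """
    if freqs is None:
        freqs = estimate_base_frequencies(aln)
    counts = _all_pair_counts(aln)

    def objective(log_k: np.ndarray) -> float:
        k1, k2 = np.exp(log_k)
        if not (1e-3 < k1 < 1e3 and 1e-3 < k2 < 1e3):
            return 1e18
        try:
            params = TN93Params(freqs, k1, k2)
            total = 0.0
            for name, c in counts.items():
                d = _solve_pair_distance(c, params, f"{name[0]}-{name[1]}")
                total += _pair_loglik(c, params, d)
            return -total
        except SaturationError:
            return 1e18

    res = minimize(objective, x0=np.log([2.0, 2.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
    k1, k2 = np.exp(res.x)
    return TN93Params(freqs, k1, k2)


def p_distances(aln: Alignment) -> DistanceMatrix:
    """Proportion of differing sites per pair (no correction)."""
    clean = complete_deletion(aln)
    n = len(clean.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = clean.rows[i][1], clean.rows[j][1]
            p = sum(a != b for a, b in zip(sa, sb)) / len(sa)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(clean.ids), d, "p_distance", clean.ncols)


def tn93_mcl_distances(aln: Alignment,
                       freqs: Sequence[float] | None = None,
                       kappa: tuple[float, float] | None = None,
                       shared_params: TN93Params | None = None,
                       model: str = "tn93_mcl") -> DistanceMatrix:
    """TN93 distances under shared composite-likelihood parameters.

    Complete deletion is applied first.  ``freqs`` and ``kappa`` (k1, k2)
    may be fixed; otherwise frequencies come from pooled counts and the two
    ratios from the pooled composite likelihood.  ``model="tn93_pairwise"``
    switches to the per-pair closed-form TN93 estimator (shared frequencies,
    pair-specific substitution proportions) for cross-checking.

    Raises :class:`SaturationError` naming the pair when a pair is too
    diverged for a finite estimate.
    """
    clean = complete_deletion(aln)
    if len(clean.rows) < 2:
        raise PhyloError("need >=2 sequences")
    if model == "tn93_pairwise":
        return _tn93_pairwise(clean, freqs)
    if model != "tn93_mcl":
        raise PhyloError(f"unknown distance model {model!r}")
    if shared_params is not None:
        params = shared_params
    else:
        f = np.asarray(freqs, dtype=float) if freqs is not None else None
        if kappa is not None:
            if f is None:
                f = estimate_base_frequencies(clean)
            params = TN93Params(f, kappa[0], kappa[1])
        else:
            params = estimate_shared_tn93(clean, f)
    n = len(clean.rows)
    d = np.zeros((n, n))
    for (ida, idb), counts in _all_pair_counts(clean).items():
        i, j = clean.ids.index(ida), clean.ids.index(idb)
        d[i, j] = d[j, i] = _solve_pair_distance(counts, params, f"{ida}-{idb}")
    meta = {"freqs": params.freqs.tolist(), "k1": params.k1, "k2": params.k2}
    return DistanceMatrix(tuple(clean.ids), d, "tn93_mcl", clean.ncols, meta)


def _tn93_pairwise(clean: Alignment,
                   freqs: Sequence[float] | None = None) -> DistanceMatrix:
    """Closed-form per-pair TN93 distances (shared base frequencies)."""
    f = (np.asarray(freqs, dtype=float) if freqs is not None
         else estimate_base_frequencies(clean))
    pA, pC, pG, pT = f
    pR, pY = pA + pG, pC + pT
    c1 = 2 * pA * pG / pR
    c2 = 2 * pT * pC / pY
    c3 = 2 * (pR * pY - pA * pG * pY / pR - pT * pC * pR / pY)
    n = len(clean.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            (ida, sa), (idb, sb) = clean.rows[i], clean.rows[j]
            L = len(sa)
            p1 = sum(1 for a, b in zip(sa, sb)
                     if {a, b} == {"A", "G"}) / L
            p2 = sum(1 for a, b in zip(sa, sb)
                     if {a, b} == {"C", "T"}) / L
            q = sum(1 for a, b in zip(sa, sb)
                    if a != b and {a, b} not in ({"A", "G"}, {"C", "T"})) / L
            w1 = 1 - p1 / c1 - q / (2 * pR)
            w2 = 1 - p2 / c2 - q / (2 * pY)
            w3 = 1 - q / (2 * pR * pY)
            if min(w1, w2, w3) <= 0:
                raise SaturationError(
                    f"pair {ida}-{idb} is saturated (log argument <= 0)"
                )
            d[i, j] = d[j, i] = max(
                0.0, -c1 * np.log(w1) - c2 * np.log(w2) - c3 * np.log(w3)
            )
    return DistanceMatrix(tuple(clean.ids), d, "tn93_pairwise", clean.ncols)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """Tree node: a labelled leaf or an internal node with (child, length) pairs."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None,
                 children: list[tuple["Node", float]] | None = None):
        self.label = label
        self.children = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf():
            return frozenset([self.label])
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaf_labels()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted tree (stored rooted at the final NJ trifurcation).

    ``supports`` maps canonical bipartition sides (frozensets of leaf
    labels) to bootstrap percentages; ``clamped`` lists nodes whose NJ
    branch-length estimate was negative and was clamped to zero.
    """

    root: Node
    labels: tuple[str, ...]
    supports: dict[frozenset, float] = field(default_factory=dict)
    clamped: list[str] = field(default_factory=list)

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical leaf-set sides of every edge of the unrooted tree."""
        n = len(self.labels)
        ref = min(self.labels)
        sides: set[frozenset] = set()

        def visit(node: Node) -> None:
            for child, _ in node.children:
                s = child.leaf_labels()
                if ref in s:
                    s = frozenset(self.labels) - s
                if include_trivial or 2 <= len(s) <= n - 2:
                    if 1 <= len(s) <= n - 1:
                        sides.add(s)
                visit(child)

        visit(self.root)
        return sides

    def newick(self, with_supports: bool = False, precision: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                return node.label
            inner = ",".join(
                f"{fmt(child)}:{length:.{precision}f}"
                for child, length in node.children
            )
            label = ""
            if with_supports and node is not self.root:
                s = node.leaf_labels()
                ref = min(self.labels)
                key = frozenset(self.labels) - s if ref in s else s
                if key in self.supports:
                    label = f"{self.supports[key]:.0f}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def neighbour_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbour joining with deterministic tie-breaking.

    The pair minimising the Q criterion is joined at each step; exact ties
    resolve to the lowest (row, column) index pair in the current matrix
    order.  Negative branch-length estimates are clamped to zero and the
    affected child recorded in ``clamped``.  The final three lineages are
    resolved by the closed-form three-point formulas, leaving a trifurcating
    root (unrooted tree).
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbour joining requires >=3 labels")
    D = dm.d.copy()
    nodes: list[Node] = [Node(label=l) for l in dm.labels]
    names: list[str] = list(dm.labels)
    clamped: list[str] = []

    def clamp(length: float, child_name: str) -> float:
        if length < 0:
            clamped.append(child_name)
            return 0.0
        return length

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li = clamp(li, names[i])
        lj = clamp(lj, names[j])
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_name = f"({names[i]},{names[j]})"
        dnew = (D[i, :] + D[j, :] - D[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [new_name]

    (a, b, c) = range(3)
    la = clamp((D[a, b] + D[a, c] - D[b, c]) / 2, names[a])
    lb = clamp((D[a, b] + D[b, c] - D[a, c]) / 2, names[b])
    lc = clamp((D[a, c] + D[b, c] - D[a, b]) / 2, names[c])
    root = Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root, labels=tuple(dm.labels), clamped=clamped)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _resample_columns(aln: Alignment, rng: np.random.Generator) -> Alignment:
    idx = rng.integers(0, aln.ncols, size=aln.ncols)
    rows = tuple(
        (rid, "".join(s[k] for k in idx)) for rid, s in aln.rows
    )
    return Alignment(rows, score=0.0)


def bootstrap_support(aln: Alignment, n_reps: int, seed: int,
                      model: str = "tn93_mcl",
                      freqs: Sequence[float] | None = None,
                      kappa: tuple[float, float] | None = None,
                      max_redraws: int = 10) -> PhyloTree:
    """Column-resampling bootstrap supports for the NJ tree of an alignment.

    The tree and (for the composite-likelihood model) the shared TN93
    parameters are estimated once from the original alignment; each of the
    ``n_reps`` replicates resamples columns with replacement, reapplies
    complete deletion, recomputes distances under the shared parameters and
    rebuilds the NJ tree.  Support for each original-tree bipartition is the
    percentage of replicate trees containing it.  Replicates whose resample
    leaves zero usable columns (or a saturated pair) are redrawn up to
    ``max_redraws`` times.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    clean = complete_deletion(aln)
    shared: TN93Params | None = None
    if model == "tn93_mcl":
        f = np.asarray(freqs, dtype=float) if freqs is not None \
            else estimate_base_frequencies(clean)
        shared = (TN93Params(f, *kappa) if kappa is not None
                  else estimate_shared_tn93(clean, f))

    def distances(a: Alignment) -> DistanceMatrix:
        if model == "p_distance":
            return p_distances(a)
        return tn93_mcl_distances(a, shared_params=shared, model="tn93_mcl")

    tree = neighbour_joining(distances(clean))
    targets = tree.bipartitions()
    hits = {s: 0 for s in targets}
    for _ in range(n_reps):
        for attempt in range(max_redraws + 1):
            try:
                rep = _resample_columns(aln, rng)
                rep_tree = neighbour_joining(distances(rep))
                break
            except (PhyloError, SaturationError):
                if attempt == max_redraws:
                    raise
        rep_sides = rep_tree.bipartitions()
        for s in targets:
            if s in rep_sides:
                hits[s] += 1
    tree.supports = {s: 100.0 * h / n_reps for s, h in hits.items()}
    return tree


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

def check_group_monophyly(tree: PhyloTree,
                          groups: Mapping[str, str]) -> dict[str, bool]:
    """Whether each group's leaves are separated by some tree bipartition.

    ``groups`` maps every leaf label to a group name.  A group is
    monophyletic on the unrooted tree iff some edge splits exactly its
    leaves from the rest (singletons and the full leaf set are trivially
    monophyletic).
    """
    leafset = set(tree.labels)
    unknown = leafset - set(groups)
    if unknown:
        raise PhyloError(f"leaves without group assignment: {sorted(unknown)}")
    sides = tree.bipartitions(include_trivial=True)
    both = sides | {frozenset(leafset) - s for s in sides}
    result = {}
    for group in sorted(set(groups.values())):
        members = frozenset(l for l, g in groups.items() if g == group)
        result[group] = (
            len(members) in (1, len(leafset)) or members in both
        )
    return result
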