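"""Phylogenetics tests: complete deletion, TN93 composite-likelihood
distances (with Jukes-Cantor analytic limit), NJ consistency on additive
matrices, bootstrap determinism and group monophyly."""

import numpy as np
import pytest

from granzymekit.align import Alignment
from granzymekit.phylo import (
    DistanceMatrix,
    PhyloError,
    SaturationError,
    TN93Params,
    _pair_counts,
    _pair_score,
    _solve_pair_distance,
    bootstrap_support,
    check_group_monophyly,
    complete_deletion,
    neighbour_joining,
    p_distances,
    tn93_mcl_distances,
)
from granzymekit.synthetic import EvolSpec, evolve_family

THREE_CLADES = ("((A1:0.02,A2:0.02):0.3,(B1:0.02,B2:0.02):0.3,"
                "(C1:0.02,C2:0.02):0.3);")


def family_alignment(spec: EvolSpec) -> Alignment:
    fam = evolve_family(spec)
    return Alignment(tuple((r.id, r.residues) for r in fam.records))


# ---------------------------------------------------------------------------
# random additive trees (ground truth for NJ consistency)
# ---------------------------------------------------------------------------

def random_additive_case(rng: np.random.Generator, n: int):
    """Random binary tree over n leaves; returns (DistanceMatrix, true
    non-trivial bipartitions, pairwise path-length dict)."""
    labels = [f"t{i}" for i in range(n)]
    active = [(frozenset([l]), {l: 0.0}) for l in labels]
    dist: dict[frozenset, float] = {}
    bipartitions: set[frozenset] = set()
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (sa, da) = active.pop(j)
        (sb, db) = active.pop(i)
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset({x, y})] = dx + la + dy + lb
        merged = {**{x: d + la for x, d in da.items()},
                  **{y: d + lb for y, d in db.items()}}
        side = sa | sb
        if 2 <= len(side) <= n - 2:
            bipartitions.add(side)
        active.append((side, merged))
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = dist[frozenset({labels[a], labels[b]})]
    ref = min(labels)
    canonical = {
        frozenset(labels) - s if ref in s else s for s in bipartitions
    }
    return DistanceMatrix(tuple(labels), d, "p_distance", 0), canonical, dist


def tree_path_lengths(tree) -> dict[frozenset, float]:
    """Pairwise leaf path lengths of a PhyloTree (independent traversal)."""
    out: dict[frozenset, float] = {}

    def leaf_depths(node):
        if node.is_leaf():
            return {node.label: 0.0}
        merged = {}
        parts = []
        for child, length in node.children:
            depths = {l: d + length for l, d in leaf_depths(child).items()}
            for prev in parts:
                for x, dx in prev.items():
                    for y, dy in depths.items():
                        out[frozenset({x, y})] = dx + dy
            parts.append(depths)
            merged.update(depths)
        return merged

    leaf_depths(tree.root)
    return out


# ---------------------------------------------------------------------------
# complete deletion
# ---------------------------------------------------------------------------

class TestCompleteDeletion:
    def test_gap_free_unchanged(self):
        aln = Alignment((("a", "ACGT"), ("b", "AGGT")))
        assert complete_deletion(aln).rows == aln.rows

    def test_single_gap_removes_exactly_that_column(self):
        aln = Alignment((("a", "ACGT"), ("b", "A-GT")))
        clean = complete_deletion(aln)
        assert clean.row("a") == "AGT"
        assert clean.row("b") == "AGT"

    def test_ambiguity_codes_also_excluded(self):
        aln = Alignment((("a", "ACNT"), ("b", "ACGT")))
        assert complete_deletion(aln).ncols == 3

    def test_all_columns_gapped_somewhere_raises(self):
        aln = Alignment((("a", "-CG"), ("b", "A-G"), ("c", "AC-")))
        with pytest.raises(PhyloError):
            complete_deletion(aln)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_identical_sequences_distance_zero(self):
        aln = Alignment((("a", "ACGT" * 20), ("b", "ACGT" * 20)))
        dm = tn93_mcl_distances(aln, kappa=(2.0, 2.0))
        assert dm.get("a", "b") == 0.0

    def test_jukes_cantor_analytic_limit(self):
        """Equal frequencies and both ratios forced to 1 collapse TN93 to
        Jukes-Cantor: d must equal -(3/4)ln(1 - 4p/3) at p = 0.1."""
        L = 1000
        a = "A" * L
        b = "G" * 100 + "A" * 900
        aln = Alignment((("x", a), ("y", b)))
        dm = tn93_mcl_distances(aln, freqs=[0.25] * 4, kappa=(1.0, 1.0))
        expected = -0.75 * np.log(1 - 4 * 0.1 / 3)
        assert abs(dm.get("x", "y") - expected) < 1e-9

    def test_correction_inflates_p_distance(self):
        aln = family_alignment(EvolSpec(seed=31, tree="(A:0.1,B:0.15);",
                                        sequence_length=5000))
        pd = p_distances(aln)
        tn = tn93_mcl_distances(aln)
        assert tn.get("A", "B") >= pd.get("A", "B")

    def test_pairwise_closed_form_agrees_with_composite(self):
        aln = family_alignment(EvolSpec(seed=32, tree="(A:0.08,B:0.08);",
                                        sequence_length=50000,
                                        freqs=(0.3, 0.2, 0.2, 0.3)))
        mcl = tn93_mcl_distances(aln)
        closed = tn93_mcl_distances(aln, model="tn93_pairwise")
        assert mcl.get("A", "B") == pytest.approx(closed.get("A", "B"),
                                                  rel=0.02)

    def test_simulated_distance_within_three_standard_errors(self):
        true_d = 0.12
        aln = family_alignment(EvolSpec(seed=33, tree="(A:0.05,B:0.07);",
                                        sequence_length=100000,
                                        k1=3.0, k2=2.0))
        dm = tn93_mcl_distances(aln)
        est = dm.get("A", "B")
        # observed-information standard error at the estimate
        params = TN93Params(dm.meta["freqs"], dm.meta["k1"], dm.meta["k2"])
        counts = _pair_counts(aln.row("A"), aln.row("B"))
        h = 1e-5
        info = -(_pair_score(counts, params, est + h)
                 - _pair_score(counts, params, est - h)) / (2 * h)
        se = 1.0 / np.sqrt(info)
        assert abs(est - true_d) < 3 * se

    def test_saturated_pair_raises_naming_pair(self):
        aln = Alignment((("sat1", "A" * 300), ("sat2", "C" * 300)))
        with pytest.raises(SaturationError, match="sat1-sat2"):
            tn93_mcl_distances(aln, freqs=[0.25] * 4, kappa=(1.0, 1.0))
        with pytest.raises(SaturationError, match="sat1-sat2"):
            tn93_mcl_distances(aln, model="tn93_pairwise", freqs=[0.25] * 4)

    def test_sites_used_recorded_after_deletion(self):
        aln = Alignment((("a", "ACGT-CGT"), ("b", "ACGTACGT")))
        dm = tn93_mcl_distances(aln, kappa=(2.0, 2.0))
        assert dm.sites_used == 7


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbour_joining(DistanceMatrix(("a", "b", "c"), d,
                                                "p_distance", 0))
        lengths = {child.label: l for child, l in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        dm, true_bips, true_dist = random_additive_case(rng, n)
        tree = neighbour_joining(dm)
        assert tree.bipartitions() == true_bips
        paths = tree_path_lengths(tree)
        for pair, d in true_dist.items():
            assert paths[pair] == pytest.approx(d, abs=1e-9)

    def test_matches_independent_nj_topology(self):
        import skbio

        rng = np.random.default_rng(99)
        dm, true_bips, _ = random_additive_case(rng, 8)
        ours = neighbour_joining(dm).bipartitions()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, list(dm.labels)))
        ref = min(dm.labels)
        sk_bips = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(dm.labels) - side
            if 2 <= len(side) <= len(dm.labels) - 2:
                sk_bips.add(side)
        assert ours == sk_bips

    def test_equal_distances_resolve_deterministically(self):
        d = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(tuple("abcde"), d, "p_distance", 0)
        t1 = neighbour_joining(dm).newick()
        t2 = neighbour_joining(dm).newick()
        assert t1 == t2

    def test_negative_branch_lengths_clamped_and_flagged(self):
        d = np.array([
            [0, 1, 10, 10],
            [1, 0, 10, 10],
            [10, 10, 0, 0.1],
            [10, 10, 0.1, 0],
        ])
        tree = neighbour_joining(DistanceMatrix(tuple("abcd"), d,
                                                "p_distance", 0))
        paths = tree_path_lengths(tree)
        assert min(paths.values()) >= 0

    def test_fewer_than_three_labels_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(PhyloError):
            neighbour_joining(DistanceMatrix(("a", "b"), d, "p_distance", 0))


# ---------------------------------------------------------------------------
# bootstrap + monophyly
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = family_alignment(EvolSpec(seed=41, tree=THREE_CLADES,
                                        sequence_length=500))
        tree = bootstrap_support(aln, n_reps=1, seed=7)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        aln = family_alignment(EvolSpec(seed=42, tree=THREE_CLADES,
                                        sequence_length=500))
        t1 = bootstrap_support(aln, n_reps=20, seed=3)
        t2 = bootstrap_support(aln, n_reps=20, seed=3)
        assert t1.supports == t2.supports

    def test_supports_invariant_to_row_order(self):
        fam = evolve_family(EvolSpec(seed=43, tree=THREE_CLADES,
                                     sequence_length=500))
        fwd = Alignment(tuple((r.id, r.residues) for r in fam.records))
        rev = Alignment(tuple((r.id, r.residues) for r in fam.records[::-1]))
        t1 = bootstrap_support(fwd, n_reps=15, seed=5)
        t2 = bootstrap_support(rev, n_reps=15, seed=5)
        assert t1.supports == t2.supports

    def test_deep_split_strongly_supported(self):
        aln = family_alignment(EvolSpec(
            seed=44, tree="((A1:0.01,A2:0.01):0.5,(B1:0.01,B2:0.01):0.5,"
                          "(C1:0.01,C2:0.01):0.01);",
            sequence_length=1000))
        tree = bootstrap_support(aln, n_reps=50, seed=9)
        a_side = frozenset({"A1", "A2"})
        key = a_side if min(tree.labels) not in a_side \
            else frozenset(tree.labels) - a_side
        assert tree.supports[key] >= 95.0


class TestMonophyly:
    def _caterpillar(self):
        newick = ("((((a1:0.05,a2:0.05):0.1,a3:0.05):0.1,"
                  "(b1:0.05,b2:0.05):0.1):0.1,c1:0.05,c2:0.05);")
        # build via distances so we exercise our own tree structure
        aln = family_alignment(EvolSpec(seed=45, tree=newick,
                                        sequence_length=2000))
        dm = tn93_mcl_distances(aln, kappa=(2.0, 2.0))
        return neighbour_joining(dm)

    def test_contiguous_blocks_all_monophyletic(self):
        tree = self._caterpillar()
        groups = {l: l[0] for l in tree.labels}
        assert all(check_group_monophyly(tree, groups).values())

    def test_swapped_leaf_breaks_monophyly(self):
        tree = self._caterpillar()
        groups = {l: l[0] for l in tree.labels}
        groups["a1"], groups["b1"] = "b", "a"
        result = check_group_monophyly(tree, groups)
        assert not result["a"]
        assert not result["b"]
        assert result["c"]

    def test_unknown_leaf_rejected(self):
        tree = self._caterpillar()
        with pytest.raises(PhyloError, match="without group"):
            check_group_monophyly(tree, {"a1": "a"})

    def test_end_to_end_three_planted_clades_recovered(self):
        aln = family_alignment(EvolSpec(seed=46, tree=THREE_CLADES,
                                        sequence_length=1000))
        dm = tn93_mcl_distances(aln)
        tree = neighbour_joining(dm)
        groups = {l: l[0] for l in tree.labels}
        assert all(check_group_monophyly(tree, groups).values())
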