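"""Seeded synthetic-data generators with ground-truth records.

Three generators cover everything the pipeline's tests need:

* :func:`make_scaffold` — granzyme-like precursor proteins built on the
  packaged chymotrypsinogen backbone with planted signal peptide, N-terminal
  motifs, catalytic triad, disulfide cysteines and S1 specificity triplet,
  plus random divergence away from the planted sites.  Because the backbone
  *is* the canonical numbering reference, planted mature positions coincide
  with canonical numbers, and numbering-map recovery is non-trivial but
  guaranteed.
* :func:`evolve_family` — nucleotide families evolved site-independently
  under a TN93 model along a user-supplied tree, for distance/NJ/bootstrap
  ground truth.
* :func:`make_gene_fixture` — genomic slices with primer-flanked exon
  structures whose expected amplicon length is known for every skip set.

Every generator takes a mandatory seed and is fully deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hallmarks import (
    DEFAULT_CYSTEINE_PAIRS, MOTIF_1_4, MOTIF_9_16, load_cleavage_model,
)
from .io_core import (
    GeneModel, GranzymeKitError, PrimerPair, SequenceRecord,
    load_chymotrypsinogen,
)
from .phylo import TN93Params

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


class SyntheticError(GranzymeKitError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# Protein scaffolds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldSpec:
    """Recipe for one granzyme-like precursor.

    ``triad`` maps canonical positions to the residue planted there (the
    default is the active triad); ``s1_triplet`` plants the S1 pocket;
    ``r192`` optionally plants the pocket-rim residue.  ``mutation_rate``
    is the per-site substitution probability applied to every *non-planted*
    mature position.
    """

    seed: int
    signal_len: int = 20
    cleavage_window_residues: str | None = None  # 13 residues ending at -1
    motif_1_4: str = MOTIF_1_4
    motif_9_16: str = MOTIF_9_16
    triad: Mapping[int, str] = field(
        default_factory=lambda: {57: "H", 102: "D", 195: "S"})
    cysteine_pairs: tuple[tuple[int, int], ...] = DEFAULT_CYSTEINE_PAIRS
    s1_triplet: Mapping[int, str] = field(
        default_factory=lambda: {189: "D", 216: "G", 226: "G"})
    r192: str | None = None
    mature_length: int = 245
    mutation_rate: float = 0.05

    def planted_positions(self) -> dict[int, str]:
        """Merged map canonical position -> planted residue.

        A position claimed by two different features is a collision and
        raises :class:`SyntheticError`.
        """
        planted: dict[int, str] = {}

        def put(pos: int, res: str, feature: str) -> None:
            if pos in planted:
                raise SyntheticError(
                    f"planted position collision at {pos} ({feature})"
                )
            if not 1 <= pos <= self.mature_length:
                raise SyntheticError(
                    f"planted position {pos} outside mature length "
                    f"{self.mature_length} ({feature})"
                )
            planted[pos] = res

        for k, res in enumerate(self.motif_1_4):
            put(1 + k, res, "motif_1_4")
        for k, res in enumerate(self.motif_9_16):
            put(9 + k, res, "motif_9_16")
        for pos, res in self.triad.items():
            put(int(pos), res, "triad")
        for a, b in self.cysteine_pairs:
            put(int(a), "C", "cysteine_pair")
            put(int(b), "C", "cysteine_pair")
        for pos, res in self.s1_triplet.items():
            put(int(pos), res, "s1_triplet")
        if self.r192 is not None:
            put(192, self.r192, "r192")
        return planted


@dataclass(frozen=True)
class ScaffoldTruth:
    """Everything planted into a scaffold, for downstream assertions."""

    query_id: str
    cleavage_position: int           # cleavage occurs after this residue
    planted: Mapping[int, str]       # canonical position -> residue
    triad: Mapping[int, str]
    cysteine_pairs: tuple[tuple[int, int], ...]
    s1_triplet: Mapping[int, str]
    r192: str | None
    expected_group: str
    mature: str
    signal: str


def _expected_group(s1: Mapping[int, str], r192: str | None) -> str:
    """Generator-side specificity call, independent of the classifier."""
    if r192 == "K" and s1.get(216) == "S":
        return "metase"
    trip = (s1.get(189), s1.get(216), s1.get(226))
    if trip == ("N", "G", "R"):
        return "aspase"
    if trip == ("D", "G", "G"):
        return "trypsin_like"
    if trip[0] in ("T", "A", "S") and trip[1] == "G" and trip[2] == "G":
        return "chymase"
    return "unclassified"


def make_scaffold(spec: ScaffoldSpec) -> tuple[SequenceRecord, ScaffoldTruth]:
    """Generate a precursor protein with all planted hallmark features.

    The mature region is the packaged chymotrypsinogen backbone (truncated
    to ``mature_length``) with planted residues written in and random
    substitutions elsewhere.  The signal peptide ends with the cleavage
    model's per-column optimal residues (window -13..-1) so the planted
    cleavage site is the matrix argmax.
    """
    if spec.signal_len < 13:
        raise SyntheticError("signal_len must be >= 13 (scoring window)")
    if not 0.0 <= spec.mutation_rate <= 1.0:
        raise SyntheticError("mutation_rate must be in [0, 1]")
    backbone, _ = load_chymotrypsinogen()
    if spec.mature_length > len(backbone.residues):
        raise SyntheticError(
            f"mature_length {spec.mature_length} exceeds backbone length "
            f"{len(backbone.residues)}"
        )
    planted = spec.planted_positions()
    rng = np.random.default_rng(spec.seed)

    mature = list(backbone.residues[:spec.mature_length])
    for pos, res in planted.items():
        mature[pos - 1] = res
    for idx in range(len(mature)):
        if (idx + 1) in planted:
            continue
        if rng.random() < spec.mutation_rate:
            alternatives = [a for a in AA20 if a != mature[idx]]
            mature[idx] = alternatives[rng.integers(len(alternatives))]
    mature_str = "".join(mature)

    if spec.cleavage_window_residues is not None:
        window = spec.cleavage_window_residues
        if len(window) != 13:
            raise SyntheticError("cleavage_window_residues must be 13 residues")
    else:
        model = load_cleavage_model()
        optimal = model.optimal_residues()
        window = "".join(optimal[p] for p in range(-13, 0))
    prefix_len = spec.signal_len - 13
    hydrophobic = "ALVIFM"
    prefix = "".join(hydrophobic[rng.integers(len(hydrophobic))]
                     for _ in range(prefix_len))
    signal = prefix + window

    query_id = f"scaffold_{spec.seed}"
    precursor = SequenceRecord(query_id, "protein", signal + mature_str,
                               description="synthetic granzyme-like precursor",
                               role="precursor")
    truth = ScaffoldTruth(
        query_id=query_id,
        cleavage_position=spec.signal_len,
        planted=planted,
        triad=dict(spec.triad),
        cysteine_pairs=tuple(spec.cysteine_pairs),
        s1_triplet=dict(spec.s1_triplet),
        r192=spec.r192,
        expected_group=_expected_group(dict(spec.s1_triplet), spec.r192),
        mature=mature_str,
        signal=signal,
    )
    return precursor, truth


# ---------------------------------------------------------------------------
# Nucleotide families under TN93
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolSpec:
    """Recipe for a simulated nucleotide family.

    ``tree`` is newick with branch lengths in substitutions/site; TN93
    parameters are base frequencies (ACGT order) and the two
    transition/transversion rate ratios.
    """

    seed: int
    tree: str
    sequence_length: int = 1000
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    k1: float = 2.0
    k2: float = 2.0

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise SyntheticError("base frequencies must sum to 1")
        if self.sequence_length < 1:
            raise SyntheticError("sequence_length must be >= 1")


@dataclass(frozen=True)
class EvolvedFamily:
    """Leaf sequences plus the generating tree and model (the ground truth)."""

    records: tuple[SequenceRecord, ...]
    tree: str
    params: TN93Params

    def leaf_distances(self) -> dict[frozenset, float]:
        """True patristic distances between all leaf pairs."""
        import dendropy

        tree = dendropy.Tree.get(data=self.tree, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        out = {}
        taxa = list(tree.taxon_namespace)
        for i, ta in enumerate(taxa):
            for tb in taxa[i + 1:]:
                out[frozenset({ta.label, tb.label})] = pdm.patristic_distance(ta, tb)
        return out


def evolve_family(spec: EvolSpec) -> EvolvedFamily:
    """Evolve sequences along a tree under TN93, site-independently.

    The root sequence is drawn from the equilibrium base frequencies; each
    branch applies the exact transition matrix P(b) = exp(Qb) per site.
    Zero-length branches copy the parent exactly.
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(data=spec.tree, schema="newick")
    except Exception as exc:
        raise SyntheticError(f"malformed newick tree: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise SyntheticError("negative branch length in tree")
    params = TN93Params(spec.freqs, spec.k1, spec.k2)
    rng = np.random.default_rng(spec.seed)
    L = spec.sequence_length
    root_seq = rng.choice(4, size=L, p=np.asarray(spec.freqs))

    def evolve_along(parent: np.ndarray, length: float) -> np.ndarray:
        if not length:
            return parent.copy()
        P = params.transition_matrix(length)
        P = P / P.sum(axis=1, keepdims=True)
        child = np.empty_like(parent)
        for state in range(4):
            mask = parent == state
            n = int(mask.sum())
            if n:
                child[mask] = rng.choice(4, size=n, p=P[state])
        return child

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    records = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        seqs[id(node)] = evolve_along(parent_seq, node.edge.length or 0.0)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{len(records)}"
            residues = "".join(_BASES[s] for s in seqs[id(node)])
            records.append(SequenceRecord(label.replace(" ", "_"), "dna",
                                          residues, role="cds"))
    if len(records) < 2:
        raise SyntheticError("tree must have >= 2 leaves")
    return EvolvedFamily(tuple(records), spec.tree, params)


# ---------------------------------------------------------------------------
# Gene fixtures for PCR / splice tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFixture:
    """A primer-flanked synthetic gene with per-skip-set amplicon truth."""

    genome: SequenceRecord
    model: GeneModel
    primers: PrimerPair
    amplicon_lengths: Mapping[frozenset, int]  # skip set -> expected bp
    triad_exon: int | None
    triad_genomic_positions: tuple[int, ...]   # codon base coordinates


def make_gene_fixture(n_exons: int,
                      exon_lengths: int | Sequence[int],
                      seed: int,
                      primer_len: int = 20,
                      primer_offsets: tuple[int, int] = (0, 0),
                      triad_exon: int | None = None,
                      intron_length: int = 150,
                      flank: int = 50,
                      gene_id: str = "synthgene") -> GeneFixture:
    """Generate a genomic slice, gene model and primer pair with known truth.

    Primers sit inside the first and last exon at the given offsets, so
    every internal skip set still amplifies; the truth table holds the
    expected amplicon length for each contiguous internal skip set
    (generator-side arithmetic, independent of the PCR engine).  When
    ``triad_exon`` is set, nine bases in the middle of that exon are
    recorded as the catalytic-triad codons.
    """
    if n_exons < 2:
        raise SyntheticError("gene fixture requires >= 2 exons")
    lengths = ([int(exon_lengths)] * n_exons if isinstance(exon_lengths, int)
               else [int(x) for x in exon_lengths])
    if len(lengths) != n_exons:
        raise SyntheticError(
            f"exon_lengths: expected {n_exons} values, got {len(lengths)}"
        )
    if min(lengths) < primer_len + max(primer_offsets):
        raise SyntheticError("exons too short for the primer placement")
    if triad_exon is not None and not 1 <= triad_exon <= n_exons:
        raise SyntheticError(f"triad_exon {triad_exon} out of range")

    rng = np.random.default_rng(seed)
    total = flank * 2 + sum(lengths) + intron_length * (n_exons - 1)
    genome_seq = "".join(_BASES[i] for i in rng.choice(4, size=total))
    exons = []
    pos = flank + 1
    for L in lengths:
        exons.append((pos, pos + L - 1))
        pos += L + intron_length
    model = GeneModel(gene_id, "chrSynth", "+", tuple(exons))
    genome = SequenceRecord("chrSynth", "dna", genome_seq, role="genomic")

    fwd_start = exons[0][0] + primer_offsets[0]
    forward = genome_seq[fwd_start - 1:fwd_start - 1 + primer_len]
    rev_end = exons[-1][1] - primer_offsets[1]
    rev_site = genome_seq[rev_end - primer_len:rev_end]
    from .pcr import reverse_complement

    primers = PrimerPair(f"{gene_id}_pair", forward,
                         reverse_complement(rev_site))

    from .pcr import contiguous_internal_skip_sets

    full = sum(lengths) - primer_offsets[0] - primer_offsets[1]
    amplicons = {}
    for skipped in contiguous_internal_skip_sets(n_exons):
        amplicons[skipped] = full - sum(lengths[k - 1] for k in skipped)

    triad_positions: tuple[int, ...] = ()
    if triad_exon is not None:
        s, e = exons[triad_exon - 1]
        mid = (s + e) // 2
        triad_positions = tuple(range(mid - 4, mid + 5))
    return GeneFixture(genome, model, primers, amplicons,
                       triad_exon, triad_positions)


# ---------------------------------------------------------------------------
# Fixture directory writer
# ---------------------------------------------------------------------------

DEFAULT_FAMILY_TREE = ("((A1:0.02,A2:0.03):0.30,(B1:0.02,B2:0.03):0.30,"
                       "(C1:0.02,C2:0.03):0.30);")


def write_fixture_dir(path: str, seed: int, n_scaffolds: int = 3) -> dict:
    """Write a complete fixture set (FASTA + GFF3 + primer TSV + truth JSON).

    Emits protein scaffolds, a TN93-evolved nucleotide family with a planted
    three-clade topology, and a PCR gene fixture.  Returns the truth record
    that is also written to ``truth.json``.
    """
    import json
    import os

    from .io_core import write_fasta, write_gff3

    os.makedirs(path, exist_ok=True)
    truth: dict = {"seed": seed}

    scaffolds, scaffold_truths = [], {}
    groups = [
        ({189: "D", 216: "G", 226: "G"}, None),
        ({189: "N", 216: "G", 226: "R"}, None),
        ({189: "T", 216: "G", 226: "G"}, None),
        ({189: "D", 216: "S", 226: "G"}, "K"),
    ]
    for k in range(n_scaffolds):
        s1, r192 = groups[k % len(groups)]
        rec, t = make_scaffold(ScaffoldSpec(seed=seed + k, s1_triplet=s1,
                                            r192=r192))
        scaffolds.append(rec)
        scaffold_truths[rec.id] = {
            "cleavage_position": t.cleavage_position,
            "expected_group": t.expected_group,
            "triad": {str(p): r for p, r in t.triad.items()},
        }
    write_fasta(scaffolds, os.path.join(path, "scaffolds.fasta"))
    truth["scaffolds"] = scaffold_truths

    family = evolve_family(EvolSpec(seed=seed, tree=DEFAULT_FAMILY_TREE,
                                    sequence_length=2000))
    write_fasta(family.records, os.path.join(path, "family.fasta"))
    truth["family"] = {
        "tree": family.tree,
        "groups": {r.id: r.id[0] for r in family.records},
    }

    fixture = make_gene_fixture(n_exons=5, exon_lengths=200,
                                seed=seed, triad_exon=4)
    write_fasta([fixture.genome], os.path.join(path, "genome.fasta"))
    write_gff3([fixture.model], os.path.join(path, "genes.gff3"))
    with open(os.path.join(path, "primers.tsv"), "w") as fh:
        fh.write("name\tforward\treverse\n")
        fh.write(f"{fixture.primers.name}\t{fixture.primers.forward}\t"
                 f"{fixture.primers.reverse}\n")
    truth["gene_fixture"] = {
        "amplicon_lengths": {
            ",".join(map(str, sorted(k))) or "full": v
            for k, v in fixture.amplicon_lengths.items()
        },
        "triad_exon": fixture.triad_exon,
        "triad_genomic_positions": list(fixture.triad_genomic_positions),
    }
    with open(os.path.join(path, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
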