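# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `granzymekit`, module by module, in the order the
pipeline runs.

## Sequence model and coordinates

Sequences are validated records over explicit alphabets: DNA admits IUPAC
ambiguity codes (stored uppercase; ambiguous codons translate to `X`);
proteins admit the 20 standard residues plus `X` and `*` (the latter only
from pseudogene-mode translation).  All genomic coordinates are 1-based
inclusive on the forward strand, matching GFF3; BED12 input is converted on
read.  Exons in a `GeneModel` are stored in genomic order; transcript
(exon-ordinal) order follows the strand, so "exon 4" of a minus-strand gene
is the fourth exon of the mRNA.  Reverse complementation is never applied
implicitly — callers control strand.

## Pairwise alignment and numbering transfer

Global alignment is Needleman–Wunsch with affine gaps (Gotoh's three-state
recursion).  Defaults: BLOSUM62 for proteins, +5/−4 (with a weak +1 for
compatible ambiguity codes) for DNA; gap open 10, extend 0.5, with the
convention that the first residue of a gap costs the open penalty and each
further residue the extend penalty.  Trace-back ties resolve match >
gap-in-B > gap-in-A, making alignments deterministic.  The implementation
is cross-checked in the test suite against exhaustive enumeration of all
alignments on tiny inputs and against an independent dynamic-programming
aligner (Biopython's `PairwiseAligner`) on random sequences.

Canonical serine-protease numbering is transferred by aligning the query to
the packaged bovine chymotrypsinogen A zymogen (245 residues; numbering is
the identity on this sequence, placing the triad at His57/Asp102/Ser195 and
the S1 pocket base at 189/216/226).  Each query residue aligned to a
reference residue inherits that number; insertions relative to the
reference stay unassigned (no 57A-style insertion codes).  If less than
50% of the reference is covered (configurable), transfer fails loudly; a
non-strict mode downgrades this to a warning for exploratory use.  Column
monotonicity of the alignment guarantees the map is strictly increasing and
injective, which is also asserted at construction.

Percent identity defaults to *aligned-columns* mode: terminal overhangs and
columns gapped in both rows are excluded from the denominator, internal
gap columns count as mismatches.  A *shorter-sequence* denominator mode is
available.  Similarity counts residue pairs with a positive
substitution-matrix score.  Reproduction of identity values computed with
other aligners carries an inherent ±1–2 percentage-point convention spread;
this package states its conventions and sticks to them.

Multiple alignment is progressive: pairwise p-distances, a
neighbour-joining guide tree (ids sorted lexicographically so ties break
deterministically), then profile–profile merges with Gotoh on column-pair
average scores.  Two inputs reduce exactly to pairwise alignment.  This is
a deliberately simple MSA — no iterative refinement — sufficient for
closely related protein families and for column-level tests; for large
divergent families a dedicated MSA tool is the better choice upstream.

## Hallmark checks

**Cleavage site.**  Candidate positions `p` (cleavage after residue `p`) in
a default search range 10–40 are scored by a position-weight matrix over
the window −13…+2 relative to the scissile bond; the argmax wins, ties to
the smallest position.  The packaged matrix is **synthetic**: it encodes
the standard qualitative signal-peptide chemistry (a hydrophobic h-region
at −13…−6, turn-favouring −5, small residues strictly preferred at −3 and
−1, near-neutral +1/+2) with a unique per-column optimum, rather than being
transcribed from a published count table.  It therefore supports
positional reasoning and the package's planted-site tests, but absolute
scores are not calibrated against curated signal-peptide datasets — for
production signal-peptide calls on real sequences, substitute a calibrated
matrix via `CleavageModel` (the JSON schema is trivial) or use the simple
(−3,−1) small-residue fallback scorer (`scorer="rule31"`).

**Motifs.**  Positions 1–4 and 9–16 of the mature chain are compared
exactly, per position, to IIGG and PHSRPYMA.  Residues are read
positionally, not through the numbering map: the consensus motif is what
defines the mature N-terminus, and this region is precisely where family
members diverge from the chymotrypsinogen reference, so alignment-derived
numbers would be circular (and empirically unstable) exactly here.  The
map-based lookup is retained for the deep, well-anchored positions (triad,
cysteines, S1 pocket).

**Triad and cysteines.**  Triad positions default to the chymotrypsinogen
standard 57/102/195 and are fully configurable; two alternative presets
(`alt-103`: 57/103/195 and `alt-45-95`: 45/95/195) cover numbering variants
in circulation for the same three residues.  A canonical position missing
from the numbering map is reported as *deleted* — a result, not an
exception, because exon-skipping variants legitimately lose triad codons.
Disulfide pairs default to (30,46), (162,180), (191,221), (130,201); a pair
is present iff both positions are assigned and both are Cys.  The
consolidated `overall_pass` requires the full triad, at least 3 cysteine
pairs (the family shows 3 or 4), and at most 2 motif mismatches out of 12
(both thresholds configurable).

## Specificity classification

Classification is a pure function of a canonical-position → residue map,
evaluated through an ordered rule cascade (first match wins) externalised
in YAML: metase (Lys192 + Ser216 → P1 Met/Leu), aspase
(Asn189‑Gly216‑Arg226 → Asp), trypsin-like (Asp189‑Gly216‑Gly226 →
Arg/Lys), chymase (Thr/Ala/Ser 189 + Gly216 + Gly226 → Phe/Tyr), else
unclassified.  The metase rule runs first because Lys192/Ser216 alone
identify granzyme M and must shadow the S1-triplet rules.  The chymase rule
accepts the small-neutral set {T, A, S} at 189.  Extended (S2/S3)
specificity positions are a user-configured list (empty by default — no
authoritative residue grid ships with the package); `compare_extended`
tabulates them across queries with a same/different flag per position.
Duodenase-style dual-specificity rules are intentionally not shipped: users
can add rows to the YAML.

## Phylogenetics

**Distances.**  The TN93 model is parameterised by equilibrium base
frequencies π and two transition/transversion rate ratios k₁ (A↔G) and k₂
(C↔T), with the rate matrix normalised to one expected substitution per
unit branch length.  In the default *composite-likelihood* mode, π comes
from pooled base counts and (k₁, k₂) maximise the sum over all sequence
pairs of the pair log-likelihood profiled over its own distance
(Nelder–Mead on log-ratios; per-pair distances by Brent root-finding on the
analytic derivative dL/dd = Σ n_xy (QP)_xy / P_xy, bracket [10⁻⁹, 20],
xtol 10⁻¹⁴).  Each reported distance is then the per-pair ML distance under
the shared parameters.  Forcing equal frequencies and k₁ = k₂ = 1 collapses
the model to Jukes–Cantor, and the ML distance equals −(3/4)ln(1 − 4p/3)
to machine precision — an analytic anchor asserted in the tests.  A
closed-form per-pair TN93 mode (`tn93_pairwise`) is provided as a
cross-check, and plain p-distances as a baseline.  Saturation (no finite
optimum, or a non-positive log argument in the closed form) raises an error
naming the offending pair rather than emitting NaN, because silent NaNs
poison neighbour joining.

**Complete deletion.**  Every column containing a gap or ambiguity code in
any row is removed before distance computation; the surviving column count
is recorded as `sites_used` on the distance matrix.

**Neighbour joining.**  Standard Q-criterion agglomeration; exact ties
resolve to the lowest (row, column) pair in current matrix order, making
star-like inputs deterministic.  Negative branch-length estimates are
clamped to zero and the affected child recorded.  The final three lineages
are resolved by the closed-form three-point formulas, leaving the
trifurcating root of an unrooted tree.  Consistency (exact recovery of
topology and path lengths from additive matrices) is property-tested on
random trees up to 12 leaves and cross-checked against scikit-bio's NJ.

**Bootstrap.**  Columns are resampled with replacement (one seeded
generator; the seed is recorded in reports); each replicate reapplies
complete deletion, recomputes distances and rebuilds the tree; support for
each original-tree bipartition is the percentage of replicates containing
it.  The shared TN93 parameters are estimated once from the original
alignment and held fixed across replicates — re-estimating two global rate
ratios from resampled columns of the same alignment changes supports
negligibly while costing an outer optimisation per replicate.  Replicates
whose resample leaves no usable columns are redrawn (bounded at 10).
Group monophyly on the final tree is a bipartition-membership test:
a group is monophyletic iff some edge separates exactly its leaves.

## In-silico PCR and splice variants

The forward primer is matched 5'→3' on the template, the reverse primer as
its reverse complement strictly downstream; IUPAC codes match when their
base expansions intersect, and mismatch tolerance is configurable (default
0, since assay primers are designed to the sequence).  The reported product
spans the first forward hit to the *last* compatible reverse hit — the
longest product, matching how a full-length band is read off a gel — with
both primers included in the length; an all-products mode exists.  Multiple
forward hits with overlapping products raise an ambiguity error listing the
hits.  The splice scan enumerates all contiguous internal exon-skip sets by
default, assembles each variant transcript, and calls functional impact
with triad loss dominating: `triad_disrupted` if any supplied triad-codon
coordinate falls in a skipped exon, else `frameshifted` if the retained
length is not a multiple of 3, else `intact`.  Amplicon-length conservation
(full minus variant equals the skipped exon total) is asserted against
generator-side arithmetic in the tests.

## Locus cartography

The span of a locus interval (start, end) is `end − start` — the difference
of the printed boundary coordinates — reported raw in bp and rounded
half-up to the nearest kb.  This convention reproduces the published kb
figures for the cattle loci (155,657 bp → 156 kb on chromosome 21;
73,940 bp → 74 kb on chromosome 20).  Intergenic gaps are
`next.start − prev.end − 1` (abutting genes → 0; overlaps → negative,
flagged).  Because a published "separated by N kb" statement is ambiguous,
`separation_measures` reports start-to-start, end-to-start and outer-span
together.  The SVG renderer shares one bp-per-pixel scale across all
tracks (set by the widest locus), draws functional genes black and
pseudogenes grey with strand-directed arrowheads, and is a pure function of
its input — re-renders are byte-identical.  The packaged cattle locus table
carries real interval boundaries, gene names, order and biotypes; per-gene
coordinates are schematic placeholders (documented in the file header), so
spans and counts are exact while intra-locus gap values are illustrative.

## Synthetic data: what it emulates, what it does not

`make_scaffold` builds precursors as signal peptide + mature chain, where
the mature chain is the chymotrypsinogen backbone with hallmark residues
planted (motifs, triad, cysteine pairs, S1 triplet, optionally 192) and
uniform random substitutions elsewhere (default rate 0.05 per site;
planted sites are never mutated).  Because the backbone *is* the numbering
reference, planted mature positions coincide with canonical numbers, so
numbering-map recovery is non-trivial (the query is diverged) but has known
truth.  The last 13 signal residues are the cleavage matrix's per-column
optima, whose alternating pattern guarantees a strict argmax at the planted
site.  Default signal length 20.  The generator emulates the conserved
architecture of the family, not real granzyme sequence statistics: no
site-specific conservation profile, no indels, no propeptide (cleavage is
modelled directly at the mature start; real granzymes carry a short
activation dipeptide that the hallmark logic does not model).

`evolve_family` draws a root from the equilibrium frequencies and evolves
sites independently along a user newick tree under the exact TN93
transition matrix per branch.  No rate heterogeneity across sites, no
indels, no selection — it provides clean ground truth for distance and
topology estimators, not realistic coding evolution.  `make_gene_fixture`
plants exons in random genomic background with primers cut from the first
and last exon and a truth table of amplicon lengths for every contiguous
internal skip set; intron splice signals and codon structure are not
modelled.  Passing tests on these generators therefore demonstrate
correctness of the estimators and the annotation logic under their stated
models, not performance on real genomic data.

All generators take a mandatory seed and are deterministic given it.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run at desk scale by choice:
100 seeded scaffolds for hallmark recovery (with a brute-force cleavage
oracle), 100 random additive matrices (4–12 leaves) for NJ consistency,
100 kb two-taxon simulations for distance recovery judged at three standard
errors (observed Fisher information at the estimate), 1 kb six-taxon
families with 200 bootstrap replicates for the planted three-clade support
check (a scaled-down replicate count; the pipeline default remains 2000),
and three 5-exon gene fixtures for the splice-variant scan.  Distance
root-finding uses xtol 10⁻¹⁴; the Jukes–Cantor anchor is asserted at
10⁻⁹; NJ path-length recovery at 10⁻⁸.

## Known limitations

* The numbering transfer is single-reference pairwise; for queries below
  ~40% identity to chymotrypsinogen a profile- or structure-based transfer
  would be more reliable (the coverage floor guards against silent misuse).
* The cleavage matrix is synthetic (see above) — positionally sound,
  not calibrated.
* Composite-likelihood ratio estimation assumes one shared substitution
  process across the family; strongly heterogeneous lineages violate this.
* The progressive MSA has no refinement stage and is not intended for
  large or deeply diverged families.
* In-silico PCR models primer identity, not thermodynamics: no melting
  temperature, dimer or efficiency modelling.
* Specificity rules are literal residue conditions; enzymes whose pocket
  chemistry departs from the four canonical patterns return
  `unclassified` rather than a guess.
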