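# granzymekit

A toolkit for annotating **granzymes** — the granule-stored serine proteases
that cytotoxic T cells and NK cells deliver into target cells to trigger
apoptosis.  When a new species' granzyme repertoire is assembled from genome
and EST evidence, the same questions recur: which canonical residues does
each candidate carry, is the catalytic machinery intact, what substrate does
the enzyme likely cleave, how do the genes group phylogenetically, do PCR
products (including exon-skipping splice variants) match prediction, and how
is each locus organised?  `granzymekit` turns that workflow into a tested,
reusable pipeline, developed around the cattle granzyme family (GzmA, O, B,
H, K, M across the trypsin-like, chymotrypsin-like and metase loci) but
applicable to any serine-protease family annotated the same way.

## What it computes

**Canonical numbering.** Serine-protease positions are conventionally given
in the chymotrypsinogen coordinate system (His57–Asp102–Ser195 catalytic
triad).  `build_numbering_map` globally aligns a query to the packaged
245-residue bovine chymotrypsinogen A reference (Needleman–Wunsch with
affine gaps, BLOSUM62, open 10 / extend 0.5) and transfers residue numbers
across aligned columns.

**Hallmark validation.** On a numbered mature chain the package checks the
N-terminal consensus motifs IIGG (positions 1–4) and PHSRPYMA (9–16), the
catalytic triad, and the conserved disulfide cysteine pairs
Cys30–Cys46, Cys162–Cys180, Cys191–Cys221 and Cys130–Cys201 (3 of 4 present
is the family norm).  Signal-peptide cleavage sites are scored with a
position-weight matrix over the window −13…+2.

**Substrate specificity.** The S1-pocket residues 189, 216, 226 plus residue
192 are classified through a first-match rule cascade (shipped as editable
YAML):

| rule | residues | group | preferred P1 |
|---|---|---|---|
| metase | Lys192 + Ser216 | metase | Met, Leu |
| aspase | Asn189‑Gly216‑Arg226 | aspase | Asp |
| trypsin‑like | Asp189‑Gly216‑Gly226 | trypsin_like | Arg, Lys |
| chymase | Thr/Ala/Ser189‑Gly216‑Gly226 | chymase | Phe, Tyr |

**Phylogenetics.** Nucleotide distances under TN93 with parameters (base
frequencies, two transition/transversion ratios) shared across all pairs by
maximising the pooled composite likelihood; gap/ambiguity columns removed by
complete deletion; neighbour-joining trees with column-bootstrap supports
and per-group monophyly flags.

**In-silico PCR and splice variants.** Transcripts assembled from
GFF3/BED12 gene models (exon ordinals in strand order), primers matched
with IUPAC expansion, amplicons sized inclusive of both primers, and every
contiguous internal exon-skip enumerated with a functional-impact call
(`intact` / `frameshifted` / `triad_disrupted` / `no_amplicon`).

**Locus cartography.** Locus spans (difference of the interval boundary
coordinates, rounded half-up to kb), gene order, strand, functional vs
pseudogene counts, intergenic gaps, and deterministic to-scale SVG maps.

A seeded synthetic-data module generates scaffold proteins with planted
hallmarks, TN93-evolved sequence families along known trees, and
primer-flanked gene fixtures — each paired with a ground-truth record.

## Worked example

```python
from granzymekit import (SequenceRecord, build_numbering_map,
                         load_chymotrypsinogen, load_packaged_loci,
                         predict_cleavage)
from granzymekit.hallmarks import check_triad
from granzymekit.specificity import classify_sequence
from granzymekit.synthetic import ScaffoldSpec, make_scaffold

precursor, truth = make_scaffold(ScaffoldSpec(seed=1))
pos, score = predict_cleavage(precursor)
print("cleavage after residue", pos)

mature = SequenceRecord(precursor.id, "protein",
                        precursor.residues[pos:], role="mature")
ref, numbers = load_chymotrypsinogen()
nmap = build_numbering_map(mature, ref, numbers)
triad = check_triad(mature, nmap)
print({name: site.observed for name, site in triad.items()})
print(classify_sequence(mature, nmap).group)

chym = load_packaged_loci()["chymotrypsin_like"]
print(chym.span_kb_rounded, "kb,", chym.functional_count, "functional genes")
```

prints

```
cleavage after residue 20
{'His': 'H', 'Asp': 'D', 'Ser': 'S'}
trypsin_like
156 kb, 10 functional genes
```

— the synthetic precursor's signal peptide is cleaved at the planted
position 20, the numbered mature chain carries the intact His57/Asp102/
Ser195 triad, its Asp189-Gly216-Gly226 pocket classifies it as trypsin-like
(P1 Arg/Lys), and the packaged cattle chymotrypsin-like locus spans 156 kb
with 10 functional genes.

The same steps are available from the shell via the `granzymekit` command
(`annotate`, `specificity`, `phylo`, `pcr`, `locus`, `fixtures`
subcommands); `granzymekit annotate run.yaml` executes the whole pipeline
from a validated YAML configuration and writes a consolidated JSON report.

## Packaged reference data

* `data/chymotrypsinogen_bovine.fasta` — bovine chymotrypsinogen A zymogen
  (UniProt P00766 sequence, 245 residues); canonical numbering is the
  identity on this sequence.
* `data/cleavage_matrix_synthetic.json` — a *synthetic* signal-peptide
  cleavage weight matrix encoding the standard qualitative chemistry
  (hydrophobic h-region, small residues at −3/−1); see `docs/methods.md`.
* `data/specificity_rules.yaml` — the default rule cascade (editable).
* `data/bovine_granzyme_loci_synthetic.tsv` — cattle locus intervals and
  gene complements with schematic per-gene coordinates (file header
  documents exactly which columns are real and which are placeholders).
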