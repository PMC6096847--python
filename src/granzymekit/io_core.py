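"""Shared data model and file I/O for the granzyme annotation pipeline.

Defines the three core record types used throughout the package
(:class:`SequenceRecord`, :class:`GeneModel`, :class:`PrimerPair`) and the
readers/writers for the external formats the pipeline touches: FASTA for
sequences, GFF3/BED12 for gene models, TSV for primer pairs and JSON/TSV for
reports.

Coordinate convention: 1-based inclusive on the forward chromosome strand,
matching GFF3.  BED input is converted on read.  Exon order stored in a
:class:`GeneModel` is genomic (ascending start); transcript order is derived
from the strand where needed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass, asdict
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# ---------------------------------------------------------------------------
# Configuration constants
# ---------------------------------------------------------------------------

#: Decimal places used for floats in TSV/JSON reports.
REPORT_FLOAT_PRECISION = 4

#: Line width used when writing FASTA.
FASTA_LINE_WIDTH = 60

#: Fraction of ACGTN characters above which a sequence is auto-typed as DNA.
DNA_DETECTION_THRESHOLD = 0.90

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = set("ACGTURYSWKMBDHVN-")

IUPAC_DNA = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class GranzymeKitError(Exception):
    """Base class for all package errors."""


class SequenceFormatError(GranzymeKitError):
    """Malformed sequence input (empty file, duplicate ids, bad characters)."""


class GeneModelError(GranzymeKitError):
    """Malformed gene model (overlapping exons, unknown strand, ...)."""


class TranslationError(GranzymeKitError):
    """CDS cannot be translated under the requested mode."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A single identified protein or nucleotide sequence.

    Parameters
    ----------
    id : str
        Accession or label; must be unique within any collection.
    alphabet : str
        Either ``"protein"`` or ``"dna"``.
    residues : str
        Sequence text; stored uppercase.  DNA may contain IUPAC ambiguity
        codes; protein may contain ``X`` and ``*`` (pseudogene translations).
    description : str
        Free-text description (FASTA header remainder).
    role : str or None
        Optional tag: ``precursor``, ``mature``, ``cds``, ``transcript`` or
        ``genomic``.
    """

    id: str
    alphabet: str
    residues: str
    description: str = ""
    role: str | None = None

    _ROLES = {"precursor", "mature", "cds", "transcript", "genomic"}

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence record requires a non-empty id")
        if self.alphabet not in ("protein", "dna"):
            raise SequenceFormatError(
                f"{self.id}: alphabet must be 'protein' or 'dna', got {self.alphabet!r}"
            )
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceFormatError(f"{self.id}: empty sequence")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise SequenceFormatError(
                f"{self.id}: illegal {self.alphabet} characters {sorted(bad)}"
            )
        if self.role is not None and self.role not in self._ROLES:
            raise SequenceFormatError(f"{self.id}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """Stranded exon structure of one gene on a chromosome.

    Exons are (start, end) pairs, 1-based inclusive, sorted by start and
    non-overlapping.  ``biotype`` distinguishes functional genes from
    pseudogenes for locus maps and reports.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "functional"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.biotype not in ("functional", "pseudogene"):
            raise GeneModelError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise GeneModelError(f"{self.gene_id}: gene model requires >=1 exon")
        for s, e in exons:
            if s > e:
                raise GeneModelError(f"{self.gene_id}: exon start {s} > end {e}")
        starts = [s for s, _ in exons]
        if starts != sorted(starts):
            raise GeneModelError(f"{self.gene_id}: exons not sorted by start")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise GeneModelError(
                    f"{self.gene_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def transcript_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order: reversed for the minus strand."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse PCR primer pair, both written 5'->3'.

    The forward primer is sense-strand; the reverse primer anneals to the
    sense strand as its reverse complement.
    """

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())
        for which, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < 10:
                raise SequenceFormatError(
                    f"primer {self.name} {which}: length {len(seq)} < 10"
                )
            bad = set(seq) - set(IUPAC_DNA)
            if bad:
                raise SequenceFormatError(
                    f"primer {self.name} {which}: illegal characters {sorted(bad)}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def detect_alphabet(residues: str) -> str:
    """Classify a sequence as dna or protein by ACGTN content."""
    s = residues.upper()
    if not s:
        raise SequenceFormatError("cannot detect alphabet of empty sequence")
    frac = sum(c in "ACGTN" for c in s) / len(s)
    return "dna" if frac >= DNA_DETECTION_THRESHOLD else "protein"


def read_fasta(path: str | os.PathLike, alphabet: str | None = None,
               role: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Alphabet is auto-detected per record (>=90% ACGTN => dna) unless
    ``alphabet`` overrides it for all records.  Duplicate ids and illegal
    characters raise :class:`SequenceFormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        alpha = alphabet or detect_alphabet(residues)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, alpha, residues, desc, role))
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, wrapped at :data:`FASTA_LINE_WIDTH` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_LINE_WIDTH)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene models (GFF3 / BED12)
# ---------------------------------------------------------------------------

def _gene_models_from_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    gene_ids = [g.id for g in db.features_of_type("gene")]
    if gene_ids:
        for gid in gene_ids:
            gene = db[gid]
            exons = sorted(
                (f.start, f.end)
                for f in db.children(gene, featuretype="exon")
            )
            if not exons:
                exons = [(gene.start, gene.end)]
            biotype = "functional"
            for key in ("biotype", "gene_biotype"):
                vals = gene.attributes.get(key, [])
                if any("pseudogene" in v for v in vals):
                    biotype = "pseudogene"
            models.append(
                GeneModel(gid, gene.seqid, gene.strand, tuple(exons), biotype)
            )
    else:
        # Exon-only GFF3: group exon features by Parent.
        groups: dict[str, list] = {}
        for f in db.features_of_type("exon"):
            parent = f.attributes.get("Parent", [f.seqid])[0]
            groups.setdefault(parent, []).append(f)
        for gid, feats in groups.items():
            exons = sorted((f.start, f.end) for f in feats)
            models.append(
                GeneModel(gid, feats[0].seqid, feats[0].strand, tuple(exons))
            )
    return models


def _gene_models_from_bed12(path: str) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise GeneModelError(
                    f"{path}:{line_no}: BED12 requires 12 fields, got {len(parts)}"
                )
            chrom, chrom_start, _, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            block_count = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise GeneModelError(f"{path}:{line_no}: block count mismatch for {name}")
            # BED is 0-based half-open; convert to 1-based inclusive.
            exons = tuple(
                (chrom_start + bs + 1, chrom_start + bs + sz)
                for bs, sz in zip(starts, sizes)
            )
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def read_gene_models(path: str | os.PathLike, dialect: str) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12.

    BED half-open 0-based coordinates are converted to the package's 1-based
    inclusive convention.  Invariant violations (overlapping exons, unknown
    strand) raise :class:`GeneModelError` naming the gene.
    """
    if dialect == "gff3":
        return _gene_models_from_gff3(str(path))
    if dialect == "bed12":
        return _gene_models_from_bed12(str(path))
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def write_bed12(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as BED12 (inverse of the bed12 reader)."""
    with open(path, "w") as fh:
        for m in models:
            chrom_start = m.start - 1
            chrom_end = m.end
            sizes = ",".join(str(e - s + 1) for s, e in m.exons)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in m.exons)
            fh.write(
                "\t".join([
                    m.chromosome, str(chrom_start), str(chrom_end), m.gene_id,
                    "0", m.strand, str(chrom_start), str(chrom_end), "0",
                    str(m.n_exons), sizes, starts,
                ]) + "\n"
            )


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            biotype = f";biotype={m.biotype}"
            fh.write("\t".join([
                m.chromosome, "granzymekit", "gene", str(m.start), str(m.end),
                ".", m.strand, ".", f"ID={m.gene_id}{biotype}",
            ]) + "\n")
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write("\t".join([
                    m.chromosome, "granzymekit", "exon", str(s), str(e),
                    ".", m.strand, ".",
                    f"ID={m.gene_id}.exon{k};Parent={m.gene_id}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# Primers
# ---------------------------------------------------------------------------

def read_primers(path: str | os.PathLike) -> list[PrimerPair]:
    """Read a primer TSV with columns ``name``, ``forward``, ``reverse``."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        try:
            idx = {k: header.index(k) for k in ("name", "forward", "reverse")}
        except ValueError as exc:
            raise SequenceFormatError(
                f"{path}: primer TSV must have name/forward/reverse columns"
            ) from exc
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            pairs.append(
                PrimerPair(parts[idx["name"]], parts[idx["forward"]], parts[idx["reverse"]])
            )
    return pairs


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate_cds(record: SequenceRecord, pseudogene_mode: bool = False) -> SequenceRecord:
    """Translate a CDS with the standard genetic code.

    A single terminal stop codon is trimmed.  An internal stop raises
    :class:`TranslationError` (reporting the 1-based codon index) unless
    ``pseudogene_mode`` is set, in which case stops are retained as ``*``.
    Ambiguous codons translate to ``X``.  Strand is the caller's
    responsibility: no implicit reverse complement is applied.
    """
    if record.alphabet != "dna":
        raise TranslationError(f"{record.id}: translate_cds requires a dna record")
    seq = record.residues.replace("U", "T")
    if len(seq) % 3 != 0:
        raise TranslationError(
            f"{record.id}: CDS length {len(seq)} not divisible by 3"
        )
    protein = str(Seq(seq).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if not pseudogene_mode and "*" in protein:
        codon_index = protein.index("*") + 1
        raise TranslationError(
            f"{record.id}: internal stop codon at codon {codon_index}"
        )
    if not protein:
        raise TranslationError(f"{record.id}: translation is empty")
    return SequenceRecord(record.id, "protein", protein, record.description, "precursor")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _to_plain(value):
    """Convert dataclasses/sets/tuples/numpy scalars to JSON-safe values."""
    import numpy as np

    if is_dataclass(value) and not isinstance(value, type):
        return {f.name: _to_plain(getattr(value, f.name)) for f in dc_fields(value)}
    if isinstance(value, Mapping):
        return {str(k): _to_plain(v) for k, v in value.items()}
    if isinstance(value, (set, frozenset)):
        return sorted(_to_plain(v) for v in value)
    if isinstance(value, (list, tuple)):
        return [_to_plain(v) for v in value]
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, float):
        return round(value, REPORT_FLOAT_PRECISION)
    return value


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.{REPORT_FLOAT_PRECISION}f}"
    if isinstance(value, (list, dict)):
        return json.dumps(value, sort_keys=True)
    return str(value)


def write_report(results: Sequence, path: str | os.PathLike, format: str = "json",
                 fields: Sequence[str] | None = None) -> None:
    """Serialise a list of result records (dataclasses or dicts) to JSON or TSV.

    Field order is deterministic: declaration order for dataclasses,
    first-seen order for dicts, or the explicit ``fields`` argument.  Floats
    are rounded to :data:`REPORT_FLOAT_PRECISION`; the same inputs always
    produce byte-identical output.
    """
    rows = [_to_plain(r) for r in results]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if fields is None:
        fields = []
        for row in rows:
            for key in row:
                if key not in fields:
                    fields.append(key)
        if not fields:
            fields = ["empty"]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row.get(f)) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference data
# ---------------------------------------------------------------------------

def _data_path(name: str) -> str:
    return os.path.join(os.path.dirname(__file__), "data", name)


def load_chymotrypsinogen() -> tuple[SequenceRecord, list[int]]:
    """Packaged bovine chymotrypsinogen A reference with canonical numbering.

    Returns the 245-residue zymogen sequence together with the canonical
    residue numbers (1..245); by construction the serine-protease numbering
    scheme is the identity on this sequence (His57, Asp102, Ser195;
    Ser189/Gly216/Gly226 at the base of the S1 pocket).
    """
    rec = read_fasta(_data_path("chymotrypsinogen_bovine.fasta"), alphabet="protein")[0]
    return rec, list(range(1, len(rec.residues) + 1))
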