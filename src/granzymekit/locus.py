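"""Locus cartography: extents, gene order, intergenic distances and
to-scale comparative SVG maps of granzyme gene loci.

Span convention: the span of a locus interval (start, end) is ``end -
start`` — the difference of the boundary coordinates — rounded half-up to
the nearest kb for reporting; the raw bp value is always retained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .io_core import GeneModel, GranzymeKitError, _data_path


class LocusError(GranzymeKitError):
    """Invalid locus-map input."""


def round_half_up_kb(span_bp: int) -> int:
    """Round a bp span to the nearest kb, halves away from zero."""
    return int(
        (Decimal(span_bp) / Decimal(1000)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# Locus map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusGene:
    gene_id: str
    start: int
    end: int
    strand: str
    biotype: str


@dataclass(frozen=True)
class LocusMap:
    """Gene order and derived statistics for one chromosomal locus."""

    species: str
    chromosome: str
    interval: tuple[int, int]
    genes: tuple[LocusGene, ...]

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if lo > hi:
            raise LocusError(f"interval start {lo} > end {hi}")
        genes = tuple(sorted(self.genes, key=lambda g: (g.start, g.gene_id)))
        object.__setattr__(self, "genes", genes)
        for g in genes:
            if g.start < lo or g.end > hi:
                raise LocusError(
                    f"gene {g.gene_id} ({g.start},{g.end}) outside locus "
                    f"interval ({lo},{hi})"
                )

    @property
    def span_bp(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def span_kb_rounded(self) -> int:
        return round_half_up_kb(self.span_bp)

    @property
    def functional_count(self) -> int:
        return sum(g.biotype == "functional" for g in self.genes)

    @property
    def pseudogene_count(self) -> int:
        return sum(g.biotype == "pseudogene" for g in self.genes)

    def summary_row(self) -> dict:
        return {
            "species": self.species,
            "chromosome": self.chromosome,
            "interval_start": self.interval[0],
            "interval_end": self.interval[1],
            "span_bp": self.span_bp,
            "span_kb": self.span_kb_rounded,
            "n_genes": len(self.genes),
            "functional": self.functional_count,
            "pseudogenes": self.pseudogene_count,
        }


def build_locus(genes: Sequence[GeneModel | LocusGene],
                interval: tuple[int, int],
                species: str = "", chromosome: str | None = None) -> LocusMap:
    """Assemble a :class:`LocusMap` from gene models inside an interval.

    Accepts :class:`~granzymekit.io_core.GeneModel` objects (exon extents
    collapsed to gene extents) or pre-built :class:`LocusGene` rows.  A gene
    outside the interval raises :class:`LocusError` naming it.
    """
    if not genes:
        raise LocusError("locus requires at least one gene")
    rows = []
    chroms = set()
    for g in genes:
        if isinstance(g, GeneModel):
            rows.append(LocusGene(g.gene_id, g.start, g.end, g.strand, g.biotype))
            chroms.add(g.chromosome)
        else:
            rows.append(g)
    if chromosome is None:
        if len(chroms) > 1:
            raise LocusError(f"genes on multiple chromosomes: {sorted(chroms)}")
        chromosome = chroms.pop() if chroms else ""
    return LocusMap(species, chromosome, (int(interval[0]), int(interval[1])),
                    tuple(rows))


# ---------------------------------------------------------------------------
# Intergenic distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntergenicGap:
    gene_a: str
    gene_b: str
    gap_bp: int

    @property
    def overlapping(self) -> bool:
        return self.gap_bp < 0


def intergenic_distances(locus: LocusMap) -> list[IntergenicGap]:
    """Gaps between adjacent genes: next.start - prev.end - 1.

    Abutting genes give 0; overlapping genes give a negative gap, flagged
    via :attr:`IntergenicGap.overlapping`.
    """
    if len(locus.genes) < 2:
        raise LocusError("intergenic distances require >=2 genes")
    out = []
    for a, b in zip(locus.genes, locus.genes[1:]):
        out.append(IntergenicGap(a.gene_id, b.gene_id, b.start - a.end - 1))
    return out


def separation_measures(locus: LocusMap, gene_a: str, gene_b: str) -> dict[str, int]:
    """Three ways to measure the separation of two locus genes.

    Published "separated by N kb" statements are ambiguous between
    start-to-start, end-to-start and outer-span measures; all three are
    returned so the user can compare.
    """
    by_id = {g.gene_id: g for g in locus.genes}
    try:
        a, b = by_id[gene_a], by_id[gene_b]
    except KeyError as exc:
        raise LocusError(f"gene {exc.args[0]!r} not in locus") from None
    if a.start > b.start:
        a, b = b, a
    return {
        "start_to_start": b.start - a.start,
        "end_to_start": b.start - a.end,
        "outer_span": b.end - a.start,
    }


# ---------------------------------------------------------------------------
# Packaged locus table
# ---------------------------------------------------------------------------

def load_packaged_loci(path: str | None = None) -> dict[str, LocusMap]:
    """Load the packaged cattle granzyme locus table, keyed by locus name.

    Interval boundaries and the gene complement are as published for the
    cattle assembly; per-gene coordinates in the packaged file are schematic
    (see the file header), so spans and counts are exact while intra-locus
    gaps are illustrative.
    """
    import csv

    path = path or _data_path("bovine_granzyme_loci_synthetic.tsv")
    grouped: dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            key = row["locus"]
            entry = grouped.setdefault(key, {
                "species": row["species"],
                "chromosome": row["chromosome"],
                "interval": (int(row["interval_start"]), int(row["interval_end"])),
                "genes": [],
            })
            entry["genes"].append(LocusGene(
                row["gene_id"], int(row["gene_start"]), int(row["gene_end"]),
                row["strand"], row["biotype"],
            ))
    return {
        key: LocusMap(e["species"], e["chromosome"], e["interval"],
                      tuple(e["genes"]))
        for key, e in grouped.items()
    }


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

_TRACK_HEIGHT = 60
_GENE_HEIGHT = 14
_MARGIN = 70
_WIDTH = 1000

_FILL = {"functional": "#000000", "pseudogene": "#9e9e9e"}


def _gene_glyph(x0: float, x1: float, y: float, strand: str, fill: str,
                label: str) -> str:
    """A gene bar with an arrowhead showing transcriptional orientation."""
    h = _GENE_HEIGHT
    head = min(6.0, max(2.0, (x1 - x0) * 0.25))
    if strand == "+":
        body = (f'<polygon points="{x0:.2f},{y:.2f} {x1 - head:.2f},{y:.2f} '
                f'{x1:.2f},{y + h / 2:.2f} {x1 - head:.2f},{y + h:.2f} '
                f'{x0:.2f},{y + h:.2f}" fill="{fill}" class="gene strand-plus"/>')
    else:
        body = (f'<polygon points="{x1:.2f},{y:.2f} {x0 + head:.2f},{y:.2f} '
                f'{x0:.2f},{y + h / 2:.2f} {x0 + head:.2f},{y + h:.2f} '
                f'{x1:.2f},{y + h:.2f}" fill="{fill}" class="gene strand-minus"/>')
    text = (f'<text x="{(x0 + x1) / 2:.2f}" y="{y - 3:.2f}" font-size="9" '
            f'text-anchor="middle">{label}</text>')
    return body + "\n" + text


def render_locus_svg(loci: Sequence[LocusMap], path: str | os.PathLike) -> None:
    """Render one to-scale track per locus into an SVG file.

    A single bp-per-pixel scale (set by the widest locus) is shared across
    all tracks, so track lengths are proportional to spans.  Functional
    genes are black, pseudogenes grey; arrowheads point in the direction of
    transcription.  Output is a pure function of the input: identical loci
    produce byte-identical files.
    """
    if not loci:
        raise LocusError("render_locus_svg requires >=1 locus")
    max_span = max(l.span_bp for l in loci) or 1
    usable = _WIDTH - 2 * _MARGIN
    scale = usable / max_span  # px per bp, shared by all tracks
    height = _TRACK_HEIGHT * len(loci) + 20
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_WIDTH}" '
        f'height="{height}" viewBox="0 0 {_WIDTH} {height}">',
    ]
    for t, locus in enumerate(loci):
        y0 = 20 + t * _TRACK_HEIGHT
        axis_y = y0 + 30
        x_start = _MARGIN
        x_end = _MARGIN + locus.span_bp * scale
        title = (f"{locus.species} chr{locus.chromosome} "
                 f"{locus.span_kb_rounded} kb")
        parts.append(f'<text x="{_MARGIN}" y="{y0:.2f}" font-size="11">'
                     f'{title}</text>')
        parts.append(f'<line x1="{x_start:.2f}" y1="{axis_y:.2f}" '
                     f'x2="{x_end:.2f}" y2="{axis_y:.2f}" '
                     f'stroke="#444444" stroke-width="1"/>')
        for g in locus.genes:
            gx0 = _MARGIN + (g.start - locus.interval[0]) * scale
            gx1 = _MARGIN + (g.end - locus.interval[0]) * scale
            parts.append(_gene_glyph(gx0, max(gx1, gx0 + 2), axis_y - _GENE_HEIGHT / 2,
                                     g.strand, _FILL[g.biotype], g.gene_id))
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
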