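"""Pipeline orchestration: validated run configuration and the full
annotation run (sequences -> numbering -> hallmarks -> specificity ->
identity matrix -> phylogeny -> PCR -> locus maps).

Stages are fail-soft across each other: a failure in one stage is recorded
in the report's ``errors`` section and the remaining independent stages
still run.  Within a stage, errors on one sequence do not abort the others.
Two runs with the same configuration and seed produce byte-identical
reports; wall-clock metadata lives in a separate ``run_metadata.json``.
"""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import align, hallmarks, io_core, locus as locus_mod, pcr as pcr_mod
from . import phylo as phylo_mod, specificity as spec_mod
from .io_core import GranzymeKitError


class ConfigError(GranzymeKitError):
    """Configuration file failed validation; message lists every violation."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class PcrConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    genome: str
    genes: str
    primers: str
    max_mismatches: int = 0
    triad_codon_positions: list[int] = Field(default_factory=list)


class RunConfig(BaseModel):
    """Validated configuration for :func:`run_pipeline`.

    Optional stages are simply omitted from the report when their inputs
    are absent.
    """

    model_config = ConfigDict(extra="forbid")

    proteins: str | None = None          # precursor/mature protein FASTA
    cds: str | None = None               # CDS FASTA, translated to proteins
    proteins_are_mature: bool = False
    family: str | None = None            # nucleotide family FASTA for phylo
    groups: dict[str, str] = Field(default_factory=dict)
    triad_preset: str = "standard"
    motif_mismatch_ceiling: int = hallmarks.DEFAULT_MOTIF_MISMATCH_CEILING
    rules_file: str | None = None
    extended_positions: list[int] = Field(default_factory=list)
    phylo_model: str = "tn93_mcl"
    bootstrap_reps: int = 2000
    seed: int = 0
    pcr: PcrConfig | None = None
    locus_table: str | None = None
    output_dir: str = "granzymekit_out"
    report_format: str = "json"

    @field_validator("bootstrap_reps")
    @classmethod
    def _reps_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        return v

    @field_validator("report_format")
    @classmethod
    def _format_known(cls, v: str) -> str:
        if v not in ("json", "tsv"):
            raise ValueError("report_format must be 'json' or 'tsv'")
        return v

    @field_validator("triad_preset")
    @classmethod
    def _preset_known(cls, v: str) -> str:
        if v not in hallmarks.TRIAD_PRESETS:
            raise ValueError(
                f"unknown triad preset {v!r}; "
                f"available: {sorted(hallmarks.TRIAD_PRESETS)}"
            )
        return v

    def input_paths(self) -> list[str]:
        paths = [self.proteins, self.cds, self.family, self.rules_file,
                 self.locus_table]
        if self.pcr:
            paths += [self.pcr.genome, self.pcr.genes, self.pcr.primers]
        return [p for p in paths if p]


def validate_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys, type errors and constraint violations are all collected
    into a single :class:`ConfigError`; missing referenced input files are
    reported the same way.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        config = RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            f"{path}: {len(lines)} configuration error(s):\n  "
            + "\n  ".join(lines)
        ) from None
    missing = [p for p in config.input_paths() if not os.path.exists(p)]
    if missing:
        raise ConfigError(f"{path}: missing input files: {missing}")
    return config


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _protein_stage(config: RunConfig, report: dict, errors: list) -> None:
    records: list[io_core.SequenceRecord] = []
    if config.proteins:
        records += io_core.read_fasta(config.proteins, alphabet="protein")
    if config.cds:
        for rec in io_core.read_fasta(config.cds, alphabet="dna"):
            try:
                records.append(io_core.translate_cds(rec))
            except GranzymeKitError as exc:
                errors.append({"stage": "translate", "id": rec.id,
                               "error": str(exc)})
    if not records:
        return
    reference, numbers = io_core.load_chymotrypsinogen()
    rules = spec_mod.load_rules(config.rules_file)
    model = hallmarks.load_cleavage_model()
    hallmark_rows, spec_rows, calls = [], [], []
    for rec in records:
        try:
            if config.proteins_are_mature:
                precursor = None
                mature = rec
            else:
                precursor = rec
                pos, _ = hallmarks.predict_cleavage(rec, model)
                mature = io_core.SequenceRecord(
                    rec.id, "protein", rec.residues[pos:], rec.description,
                    "mature")
            nmap = align.build_numbering_map(mature, reference, numbers,
                                            strict=False)
            hreport = hallmarks.evaluate_hallmarks(
                mature, nmap, precursor=precursor, cleavage_model=model,
                triad_positions=config.triad_preset,
                motif_mismatch_ceiling=config.motif_mismatch_ceiling)
            call = spec_mod.classify_sequence(
                mature, nmap, rules=rules,
                extended_positions=config.extended_positions)
            hallmark_rows.append(hreport.summary_row())
            spec_rows.append(call.summary_row())
            calls.append(call)
        except GranzymeKitError as exc:
            errors.append({"stage": "annotate", "id": rec.id,
                           "error": str(exc)})
    report["hallmarks"] = hallmark_rows
    report["specificity"] = spec_rows
    if config.extended_positions and len(calls) >= 2:
        table = spec_mod.compare_extended(calls)
        report["extended_comparison"] = table.to_dict(orient="records")
    if len(records) >= 2:
        matures = []
        for rec in records:
            matures.append(rec)
        try:
            im = align.build_identity_matrix(records)
            report["identity"] = {
                "labels": list(im.labels),
                "identity": [[round(float(x), 2) for x in row]
                             for row in im.identity],
                "similarity": [[round(float(x), 2) for x in row]
                               for row in im.similarity],
            }
        except GranzymeKitError as exc:
            errors.append({"stage": "identity", "error": str(exc)})


def _phylo_stage(config: RunConfig, report: dict, errors: list) -> None:
    if not config.family:
        return
    records = io_core.read_fasta(config.family, alphabet="dna")
    lengths = {len(r.residues) for r in records}
    if len(lengths) == 1:
        aln = align.Alignment(tuple((r.id, r.residues) for r in records))
    else:
        aln = align.progressive_msa(records)
    clean = phylo_mod.complete_deletion(aln)
    dm = phylo_mod.tn93_mcl_distances(aln, model=config.phylo_model) \
        if config.phylo_model != "p_distance" else phylo_mod.p_distances(aln)
    tree = phylo_mod.bootstrap_support(
        aln, n_reps=config.bootstrap_reps, seed=config.seed,
        model=config.phylo_model)
    section: dict[str, Any] = {
        "model": dm.model,
        "sites_used": dm.sites_used,
        "labels": list(dm.labels),
        "distances": [[round(float(x), 6) for x in row] for row in dm.d],
        "newick": tree.newick(with_supports=True),
        "seed": config.seed,
        "bootstrap_reps": config.bootstrap_reps,
        "clamped_branches": tree.clamped,
    }
    if config.groups:
        section["monophyly"] = phylo_mod.check_group_monophyly(
            tree, config.groups)
    report["phylo"] = section


def _pcr_stage(config: RunConfig, report: dict, errors: list) -> None:
    if not config.pcr:
        return
    genome = io_core.read_fasta(config.pcr.genome, alphabet="dna")[0]
    models = io_core.read_gene_models(config.pcr.genes, "gff3")
    primers = io_core.read_primers(config.pcr.primers)
    rows = []
    for model in models:
        for pair in primers:
            try:
                results = pcr_mod.splice_variant_scan(
                    model, genome, pair,
                    triad_codon_positions=config.pcr.triad_codon_positions,
                    max_mismatches=config.pcr.max_mismatches)
                rows += [r.summary_row() for r in results]
            except GranzymeKitError as exc:
                errors.append({"stage": "pcr", "id": model.gene_id,
                               "error": str(exc)})
    report["pcr"] = rows


def _locus_stage(config: RunConfig, report: dict, errors: list) -> None:
    if not config.locus_table:
        return
    loci = locus_mod.load_packaged_loci(config.locus_table)
    rows, gaps = [], []
    ordered = [loci[k] for k in sorted(loci)]
    for name in sorted(loci):
        locus = loci[name]
        row = locus.summary_row()
        row["locus"] = name
        rows.append(row)
        if len(locus.genes) >= 2:
            gaps += [{"locus": name, "gene_a": g.gene_a, "gene_b": g.gene_b,
                      "gap_bp": g.gap_bp}
                     for g in locus_mod.intergenic_distances(locus)]
    report["loci"] = rows
    report["intergenic"] = gaps
    svg_path = os.path.join(config.output_dir, "locus_map.svg")
    locus_mod.render_locus_svg(ordered, svg_path)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the consolidated report.

    Returns the report dict; serialised copies land in ``output_dir`` as
    ``report.json`` (or ``.tsv`` per section) plus ``run_metadata.json``
    carrying the config hash, seed, package version and timestamp.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed}
    errors: list[dict] = []
    for stage in (_protein_stage, _phylo_stage, _pcr_stage, _locus_stage):
        try:
            stage(config, report, errors)
        except GranzymeKitError as exc:
            errors.append({"stage": stage.__name__.strip("_"),
                           "error": str(exc)})
    report["errors"] = errors

    out = os.path.join(config.output_dir, "report.json")
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if config.report_format == "tsv":
        for section in ("hallmarks", "specificity", "pcr", "loci"):
            if section in report and report[section]:
                io_core.write_report(
                    report[section],
                    os.path.join(config.output_dir, f"{section}.tsv"),
                    format="tsv")

    from . import __version__

    meta = {
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(os.path.join(config.output_dir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    return report
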