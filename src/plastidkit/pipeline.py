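"""Pipeline configuration and stage orchestration.

``run_pipeline`` executes the analysis stages in their natural order —
structure → codon usage → repeats → mapping → expression → editing → sRNA —
writing one stamped TSV per stage.  Stages are independent where their
inputs allow: a partial run requesting only some stages produces only those
reports, and a rerun skips stages whose outputs already exist unless
``force`` is set.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import ConfigError

logger = logging.getLogger("plastidkit")

STAGE_ORDER = (
    "structure", "codon_usage", "repeats", "map", "expression", "editing", "srna"
)


class PipelineConfig(BaseModel):
    """All paths and stage parameters; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    fasta: Optional[str] = None
    gff3: Optional[str] = None
    rna_fastq: Optional[str] = None
    rna_sam: Optional[str] = None
    srna_fastq: Optional[str] = None
    predicted_sites: Optional[str] = None
    out_dir: str = "plastidkit_out"
    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))

    min_ir_length: int = 1000
    repeat_min_length: int = 20
    repeat_max_e_value: float = 1e-3
    max_mismatch: int = 2
    srna_max_mismatch: int = 0
    multimap_policy: Literal["all", "primary"] = "all"
    min_coverage: int = 5
    min_alt_fraction: float = 0.1
    srna_min_reads: int = 20
    srna_enrichment_ratio: float = 5.0
    srna_merge_gap: int = 10
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigError(str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the requested stages; returns stage -> report path."""
    from . import editing as ed
    from . import expression as ex
    from . import genome as gn
    from . import io as pio
    from . import mapping as mp
    from . import repeats as rp
    from . import srna as sr

    logging.basicConfig(level=config.log_level)
    for stage in config.stages:
        if stage not in STAGE_ORDER:
            raise ConfigError(f"unknown stage {stage!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, Path] = {}

    genome = pio.read_fasta(config.fasta) if config.fasta else None
    annotation = pio.read_gff3(config.gff3) if config.gff3 else []
    partition = None

    def wants(stage: str) -> bool:
        return stage in config.stages

    def fresh(path: Path) -> bool:
        return config.force or not path.exists()

    if genome is not None and (wants("structure") or wants("repeats")):
        try:
            partition = gn.detect_quadripartite(genome, config.min_ir_length)
        except gn.NoInvertedRepeat:
            partition = None
            logger.warning("no inverted repeat found; structure stage skipped")

    if wants("structure") and partition is not None:
        path = out / "structure.tsv"
        if fresh(path):
            pio.write_structure_tsv(
                partition, genome, path, min_ir_length=config.min_ir_length
            )
            logger.info("structure: wrote %s (min_ir_length=%d)", path, config.min_ir_length)
        reports["structure"] = path

    if wants("codon_usage") and genome is not None and annotation:
        path = out / "codon_usage.tsv"
        if fresh(path):
            table = gn.codon_usage(annotation, genome)
            pio.write_codon_usage_tsv(table, path)
            logger.info("codon_usage: %d codons", table.total)
        reports["codon_usage"] = path

    if wants("repeats") and genome is not None:
        path = out / "repeats.tsv"
        if fresh(path):
            hits = rp.find_maximal_repeats(
                genome, config.repeat_min_length, config.repeat_max_e_value,
                partition=partition,
            )
            for h in hits:
                h.location_class = rp.classify_repeat_location(h, annotation)
            pio.write_repeats_tsv(
                hits, path, min_length=config.repeat_min_length,
                max_e_value=config.repeat_max_e_value,
            )
            logger.info("repeats: %d hits", len(hits))
        reports["repeats"] = path

    result = reads = None
    if genome is not None and (wants("map") or wants("expression") or wants("editing")):
        if config.rna_sam:
            result, reads = pio.read_sam(config.rna_sam)
        elif config.rna_fastq:
            read_list = pio.read_fastq(config.rna_fastq)
            result = mp.map_reads(read_list, genome, max_mismatch=config.max_mismatch)
            reads = {r.id: r for r in read_list}
            if wants("map"):
                path = out / "alignments.sam"
                if fresh(path):
                    pio.write_sam(result, reads, genome, path)
                reports["map"] = path

    if wants("expression") and result is not None and annotation:
        path = out / "expression.tsv"
        if fresh(path):
            records = ex.profile_expression(
                result.alignments, reads, annotation, config.multimap_policy
            )
            pio.write_expression_tsv(records, path, policy=config.multimap_policy)
            logger.info("expression: %d genes", len(records))
        reports["expression"] = path

    if wants("editing") and result is not None:
        path = out / "editing.tsv"
        if fresh(path):
            pile = mp.build_pileup(result.alignments, reads, genome)
            sites = ed.call_editing_sites(
                pile, genome, annotation,
                min_coverage=config.min_coverage,
                min_alt_fraction=config.min_alt_fraction,
            )
            pio.write_editing_tsv(
                sites, path, min_coverage=config.min_coverage,
                min_alt_fraction=config.min_alt_fraction,
            )
            logger.info("editing: %d sites", len(sites))
        reports["editing"] = path

    if wants("srna") and genome is not None and config.srna_fastq:
        path = out / "srna.tsv"
        if fresh(path):
            sreads = pio.read_fastq(config.srna_fastq)
            sresult = mp.map_reads(sreads, genome, max_mismatch=config.srna_max_mismatch)
            short, long_ = sr.size_stratified_coverage(
                sresult.alignments, sreads, len(genome)
            )
            loci = sr.call_srna_loci(
                short, long_,
                min_reads=config.srna_min_reads,
                enrichment_ratio=config.srna_enrichment_ratio,
                merge_gap=config.srna_merge_gap,
                alignments=sresult.alignments, reads=sreads,
            )
            for locus in loci:
                locus.location_class = sr.classify_locus_location(locus, annotation)
            pio.write_srna_tsv(
                loci, path, min_reads=config.srna_min_reads,
                enrichment_ratio=config.srna_enrichment_ratio,
                merge_gap=config.srna_merge_gap,
            )
            pio.write_srna_bed(loci, genome.id, out / "srna.bed")
            logger.info("srna: %d loci", len(loci))
        reports["srna"] = path

    return reports
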