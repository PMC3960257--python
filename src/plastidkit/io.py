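"""Standard-format readers and writers.

FASTA and FASTQ go through Biopython's SeqIO, SAM through pysam (a minimal
dialect: @SQ header, strand/pair flags, NM tag), GFF3 through gffutils.
GFF3 and SAM coordinates are converted to/from the package's 1-based
inclusive convention at this boundary only (GFF3 and SAM are themselves
1-based inclusive; BED exports are 0-based half-open per the BED standard).

Every TSV report opens with a comment line stamping the tool version and the
parameter values used, so a table can always be traced back to its run.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .exceptions import MalformedRecord
from .genome import (
    GeneModel,
    Interval,
    Plastome,
    RegionPartition,
    revcomp,
    translate_codon,
)
from .mapping import Alignment, MappingResult, Read
from .repeats import RepeatHit
from .srna import SRNALocus


# -- FASTA ------------------------------------------------------------------

def read_fasta(path, circular: bool = True) -> Plastome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedRecord(f"no FASTA records in {path}")
    rec = records[0]
    return Plastome(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_fasta(genome: Plastome, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
        str(path),
        "fasta",
    )


# -- FASTQ ------------------------------------------------------------------

def read_fastq(path) -> list[Read]:
    reads = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            rid = rec.id
            mate = None
            if rid.endswith("/1"):
                mate = 1
            elif rid.endswith("/2"):
                mate = 2
            reads.append(Read(id=rid, bases=str(rec.seq).upper(), mate=mate))
    except ValueError as exc:
        raise MalformedRecord(str(exc), line=len(reads) * 4 + 1) from exc
    return reads


def write_fastq(reads: Sequence[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{'I' * len(r.bases)}\n")


# -- GFF3 -------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], genome_id: str, path) -> None:
    """One feature line per exon, grouped by gene ID; ``exon_number``
    preserves transcript order and ``trans_splicing`` / ``ir_copy_of`` ride
    along as attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            for i, e in enumerate(g.exons):
                attrs = [f"ID={g.name}.exon{i + 1}", f"Parent={g.name}",
                         f"gene_type={g.type}", f"exon_number={i + 1}"]
                if g.trans_spliced:
                    attrs.append("trans_splicing=true")
                if g.ir_copy_of:
                    attrs.append(f"ir_copy_of={g.ir_copy_of}")
                if g.region:
                    attrs.append(f"region={g.region}")
                if g.pseudo:
                    attrs.append("pseudogene=true")
                strand = g.strand_of_exon(i)
                fh.write(
                    f"{genome_id}\tplastidkit\t{g.type}\t{e.start}\t{e.end}\t.\t"
                    f"{strand}\t0\t{';'.join(attrs)}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, id_spec="ID",
    )
    by_gene: dict[str, list] = {}
    order: list[str] = []
    for feat in db.all_features():
        parent = feat.attributes.get("Parent", [feat.id])[0]
        if parent not in by_gene:
            by_gene[parent] = []
            order.append(parent)
        by_gene[parent].append(feat)
    genes = []
    for name in order:
        feats = sorted(
            by_gene[name], key=lambda f: int(f.attributes.get("exon_number", ["1"])[0])
        )
        f0 = feats[0]
        strands = [f.strand for f in feats]
        genes.append(
            GeneModel(
                name=name,
                type=f0.attributes.get("gene_type", [f0.featuretype])[0],
                strand=strands[0],
                exons=[Interval(f.start, f.end) for f in feats],
                trans_spliced=f0.attributes.get("trans_splicing", ["false"])[0] == "true",
                ir_copy_of=f0.attributes.get("ir_copy_of", [None])[0],
                region=f0.attributes.get("region", [None])[0],
                pseudo=f0.attributes.get("pseudogene", ["false"])[0] == "true",
                exon_strands=strands if len(set(strands)) > 1 else None,
            )
        )
    return genes


# -- SAM --------------------------------------------------------------------

def write_sam(
    result: MappingResult | Sequence[Alignment],
    reads: Sequence[Read] | Mapping[str, Read],
    genome: Plastome,
    path,
) -> None:
    alignments = result.alignments if isinstance(result, MappingResult) else list(result)
    lookup = reads if isinstance(reads, Mapping) else {r.id: r for r in reads}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": genome.id, "LN": len(genome)}],
            "PG": [{"ID": "plastidkit", "PN": "plastidkit", "VN": __version__}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            read = lookup[aln.read_id]
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.id.rsplit("/", 1)[0] if read.mate else read.id
            flag = 0
            if aln.strand == "-":
                flag |= 16
            if read.mate:
                flag |= 1 | (64 if read.mate == 1 else 128)
            seg.flag = flag
            seg.reference_id = 0
            seg.reference_start = aln.start - 1  # SAM via pysam is 0-based here
            seg.mapping_quality = 0 if aln.multi_hits > 1 else 60
            seg.cigarstring = f"{len(read)}M"
            seg.query_sequence = read.bases if aln.strand == "+" else revcomp(read.bases)
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(read))
            seg.set_tag("NM", aln.mismatches)
            out.write(seg)


def read_sam(path) -> tuple[MappingResult, dict[str, Read]]:
    """Alignments plus reconstructed reads (read bases restored to original
    orientation from the SAM's forward-strand SEQ)."""
    alignments: list[Alignment] = []
    reads: dict[str, Read] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            mate = 1 if seg.is_read1 else 2 if seg.is_read2 else None
            rid = seg.query_name + (f"/{mate}" if mate else "")
            strand = "-" if seg.is_reverse else "+"
            bases = seg.query_sequence
            if strand == "-":
                bases = revcomp(bases)
            if rid not in reads:
                reads[rid] = Read(
                    id=rid, bases=bases, mate=mate,
                    fragment_id=seg.query_name if mate else None,
                )
            alignments.append(
                Alignment(
                    read_id=rid,
                    start=seg.reference_start + 1,
                    strand=strand,
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    length=len(bases),
                )
            )
    return MappingResult(alignments=alignments), reads


# -- TSV / BED reports ------------------------------------------------------

def _stamp(params: Mapping) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# plastidkit {__version__} {kv}".rstrip() + "\n"


def _write_table(df: pd.DataFrame, path, params: Mapping) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(params))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_structure_tsv(partition: RegionPartition, genome: Plastome, path, **params):
    from .genome import gc_content

    rows = []
    for name in ("lsc", "irb", "ssc", "ira"):
        iv: Interval = getattr(partition, name)
        rows.append(
            {
                "region": name.upper(),
                "start": iv.start,
                "end": iv.end,
                "length": iv.length(len(genome)),
                "gc": round(gc_content(genome, iv), 4) if not iv.wraps else "",
            }
        )
    _write_table(pd.DataFrame(rows), path, params)


def write_codon_usage_tsv(table, path, **params):
    rows = [
        {
            "codon": codon,
            "count": count,
            "amino_acid": translate_codon(codon),
            "tRNA": table.anticodon_map.get(codon, ""),
        }
        for codon, count in sorted(table.counts.items())
    ]
    _write_table(pd.DataFrame(rows), path, params)


def write_repeats_tsv(hits: Sequence[RepeatHit], path, **params):
    rows = [
        {
            "orientation": h.orientation,
            "length": h.length,
            "pos1": h.pos1,
            "pos2": h.pos2,
            "e_value": f"{h.e_value:.3e}",
            "size_bin": h.size_bin,
            "location": h.location_class or "",
        }
        for h in hits
    ]
    _write_table(pd.DataFrame(rows, columns=[
        "orientation", "length", "pos1", "pos2", "e_value", "size_bin", "location"
    ]), path, params)


def write_expression_tsv(records, path, **params):
    rows = [
        {
            "gene": r.gene,
            "start": r.locus.start,
            "end": r.locus.end,
            "fragments": r.fragment_count,
            "fpkm": round(r.fpkm, 2),
        }
        for r in records
    ]
    _write_table(pd.DataFrame(rows, columns=["gene", "start", "end", "fragments", "fpkm"]),
                 path, params)


def write_editing_tsv(sites, path, **params):
    rows = [
        {
            "gene": s.gene,
            "position_in_gene": s.position_in_gene if s.position_in_gene else "",
            "genomic_position": s.genomic_position,
            "conversion": s.conversion,
            "codon_change": ">".join(s.codon_change) if s.codon_change else "",
            "aa_change": ">".join(s.aa_change) if s.aa_change else "",
            "synonymous": s.synonymous if s.synonymous is not None else "",
            "efficiency_pct": s.efficiency,
            "base_counts": ",".join(f"{b}:{c}" for b, c in sorted(s.base_counts.items())),
        }
        for s in sites
    ]
    _write_table(pd.DataFrame(rows, columns=[
        "gene", "position_in_gene", "genomic_position", "conversion",
        "codon_change", "aa_change", "synonymous", "efficiency_pct", "base_counts",
    ]), path, params)


def write_srna_tsv(loci: Sequence[SRNALocus], path, **params):
    rows = [
        {
            "start": x.start,
            "end": x.end,
            "strand": x.strand,
            "core_sequence": x.core_sequence or "",
            "core_length": x.core_length or "",
            "reads": x.read_count,
            "location": x.location_class or "",
        }
        for x in loci
    ]
    _write_table(pd.DataFrame(rows, columns=[
        "start", "end", "strand", "core_sequence", "core_length", "reads", "location",
    ]), path, params)


def write_srna_bed(loci: Sequence[SRNALocus], genome_id: str, path) -> None:
    """BED6 export, 0-based half-open per the BED standard."""
    with open(path, "w") as fh:
        for x in loci:
            name = x.core_sequence or f"locus_{x.start}"
            fh.write(
                f"{genome_id}\t{x.start - 1}\t{x.end}\t{name}\t{x.read_count}\t{x.strand}\n"
            )
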