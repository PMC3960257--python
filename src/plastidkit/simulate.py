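"""Synthetic plastome, annotation and read-set generator with known ground
truth.

Every generator is deterministic per seed (identical configuration + seed
produces byte-identical output) and returns, next to its artifacts, a truth
object from which downstream recovery tests read the planted features.

Default study conditions emulated here: a circular quadripartite genome
(LSC + IRb + SSC + IRa with IRa the exact reverse complement of IRb) at
~38% GC; annotated genes, some intron-containing, some IR-duplicated, one
optionally trans-spliced; paired-end mRNA-seq fragments of fixed length with
planted editing sites of specified per-molecule efficiency and a uniform
substitution error rate (default 0.1%); and small-RNA reads stacked at
planted footprint loci (20-24 nt with +/-2 nt end jitter around a core
sequence) over a background of 31-35 nt fragments tiled across abundant
genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InsufficientSpace
from .genome import GeneModel, Interval, Plastome, RegionPartition, revcomp

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PlantedEdit:
    genomic_position: int
    ref_base: str
    alt_base: str
    efficiency: float
    gene: str | None = None


@dataclass
class PlantedFootprint:
    start: int
    end: int
    strand: str
    core_sequence: str
    depth: int


@dataclass
class SimulationTruth:
    """Complete ground truth for one simulated data set."""

    rng_seed: int
    partition: RegionPartition | None = None
    genes: list[GeneModel] = field(default_factory=list)
    expression_rates: dict[str, float] = field(default_factory=dict)
    fragment_counts: dict[str, int] = field(default_factory=dict)
    edits: list[PlantedEdit] = field(default_factory=list)
    footprints: list[PlantedFootprint] = field(default_factory=list)
    n_short_reads: int = 0
    n_long_reads: int = 0

    def to_json(self, path) -> None:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=default)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def make_plastome(
    lsc_len: int = 5000,
    ssc_len: int = 800,
    ir_len: int = 1000,
    gc: float = 0.38,
    seed: int = 0,
) -> tuple[Plastome, RegionPartition]:
    """A circular quadripartite genome LSC + IRb + SSC + IRa with the planted
    partition as truth.

    The last SSC base is patched when needed so that the planted IR pair is
    maximal exactly at its boundaries (otherwise the flanking bases could
    extend the reverse-complement match by chance and shift the detected
    boundary).
    """
    if min(lsc_len, ssc_len, ir_len) <= 0 or not 0 < gc < 1:
        raise ValueError("lengths must be positive and 0 < gc < 1")
    rng = np.random.default_rng(seed)
    lsc = _random_seq(rng, lsc_len, gc)
    ir = _random_seq(rng, ir_len, gc)
    ssc = list(_random_seq(rng, ssc_len, gc))
    # maximality guard: first SSC base must not pair with the last SSC base
    if ssc_len >= 2 and ssc[0] == _COMPLEMENT[ssc[-1]]:
        ssc[-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ssc[-1]]
    ssc = "".join(ssc)
    sequence = lsc + ir + ssc + revcomp(ir)
    genome = Plastome(id=f"synthetic_plastome_seed{seed}", sequence=sequence)
    n = len(sequence)
    partition = RegionPartition(
        lsc=Interval(1, lsc_len),
        irb=Interval(lsc_len + 1, lsc_len + ir_len),
        ssc=Interval(lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len),
        ira=Interval(n - ir_len + 1, n),
    )
    return genome, partition


def plant_genes(
    genome: Plastome,
    partition: RegionPartition,
    n_genes: int = 10,
    n_intron_genes: int = 2,
    n_ir_duplicates: int = 0,
    include_trans_spliced: bool = False,
    seed: int = 0,
    gene_length: int = 300,
    intron_length: int = 120,
    spacing: int = 60,
) -> tuple[list[GeneModel], SimulationTruth]:
    """Lay out non-overlapping CDS genes on the genome.

    ``n_genes`` counts single-copy genes placed in the LSC (and SSC when the
    LSC fills up); the first ``n_intron_genes`` of them get a single intron;
    IR duplicates are placed at mirrored coordinates of the two IR copies
    (opposite strands, identical transcript sequence); the trans-spliced
    gene, when requested, has its 5' exon early in the LSC and its 3' exon
    downstream, with no intron at the junction.  All CDS lengths are
    multiples of 3.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor = partition.lsc.start + spacing
    reserve = 0
    if include_trans_spliced:
        # 5' exon of the trans-spliced gene occupies the very start of the LSC
        exon1 = Interval(partition.lsc.start + 10, partition.lsc.start + 10 + 117 - 1)
        cursor = exon1.end + spacing
        reserve = 1
    for i in range(n_genes):
        with_intron = i < n_intron_genes
        strand = "+" if i % 2 == 0 else "-"
        if with_intron:
            e1 = gene_length // 2 // 3 * 3
            e2 = gene_length - e1
            total = e1 + intron_length + e2
        else:
            total = gene_length
        if cursor + total > partition.lsc.end - spacing:
            cursor = partition.ssc.start + spacing
            if cursor + total > partition.ssc.end - spacing:
                raise InsufficientSpace(f"no room for gene {i + 1} of {n_genes}")
        start = cursor
        if with_intron:
            ex = [Interval(start, start + e1 - 1),
                  Interval(start + e1 + intron_length, start + total - 1)]
            if strand == "-":
                ex = ex[::-1]
        else:
            ex = [Interval(start, start + total - 1)]
        region = "LSC" if partition.lsc.contains(start) else "SSC"
        genes.append(GeneModel(name=f"gene{i + 1:02d}", type="CDS", strand=strand,
                               exons=ex, region=region))
        cursor += total + spacing
    if include_trans_spliced:
        exon2_start = cursor
        exon2 = Interval(exon2_start, exon2_start + 231 - 1)
        if exon2.end > partition.lsc.end:
            raise InsufficientSpace("no room for the trans-spliced 3' exon")
        genes.append(
            GeneModel(name="tsp01", type="CDS", strand="+",
                      exons=[exon1, exon2], trans_spliced=True, region="LSC")
        )
    ir_len = partition.irb.length()
    for d in range(n_ir_duplicates):
        glen = gene_length
        offset = spacing + d * (glen + spacing)
        if offset + glen + spacing > ir_len:
            raise InsufficientSpace(f"no room for IR duplicate {d + 1}")
        b = Interval(partition.irb.start + offset, partition.irb.start + offset + glen - 1)
        # mirrored coordinates in IRa, opposite strand
        a_end = partition.ira.end - offset
        a = Interval(a_end - glen + 1, a_end)
        genes.append(GeneModel(name=f"dup{d + 1:02d}", type="CDS", strand="+",
                               exons=[b], region="IR"))
        genes.append(GeneModel(name=f"dup{d + 1:02d}_ira", type="CDS", strand="-",
                               exons=[a], region="IR", ir_copy_of=f"dup{d + 1:02d}"))
    truth = SimulationTruth(rng_seed=seed, partition=partition, genes=list(genes))
    return genes, truth


def simulate_rnaseq(
    genome: Plastome,
    annotation: Sequence[GeneModel],
    expression_rates: dict[str, float],
    editing_sites: Sequence[tuple[int, float]] = (),
    read_len: int = 75,
    n_fragments: int = 2000,
    fragment_len: int = 300,
    error_rate: float = 0.001,
    seed: int = 0,
):
    """Paired-end mRNA-seq fragments with planted editing.

    Fragments are drawn per gene with probability proportional to
    rate x coding length, placed uniformly along the spliced transcript.
    Each fragment (molecule) covering a planted site carries the alternate
    base with probability equal to the site's efficiency; uniform
    substitution errors are then applied per base.  Editing sites are given
    as (genomic position, efficiency); the alternate base is U for a C
    reference (the canonical plastid conversion) and a seeded random
    different base otherwise.

    Returns (reads, truth) where reads is a list of
    :class:`plastidkit.mapping.Read` mate pairs.
    """
    from .mapping import Read  # local import to avoid a cycle at module load

    rng = np.random.default_rng(seed)
    genes = {g.name: g for g in annotation}
    expressed = [g for g in expression_rates if expression_rates[g] > 0]
    weights = np.array(
        [expression_rates[g] * genes[g].coding_length for g in expressed], float
    )
    weights /= weights.sum()
    per_gene = rng.multinomial(n_fragments, weights)

    edit_by_pos: dict[int, PlantedEdit] = {}
    for pos, eff in editing_sites:
        ref = genome.base(pos)
        if ref == "C":
            alt = "T"
        else:
            alt = rng.choice([b for b in "ACGT" if b != ref])
        host = next(
            (g.name for g in annotation if any(e.contains(pos) for e in g.exons)), None
        )
        edit_by_pos[pos] = PlantedEdit(pos, ref, str(alt), float(eff), host)

    reads: list[Read] = []
    frag_counts: dict[str, int] = {g: int(c) for g, c in zip(expressed, per_gene)}
    fid = 0
    for gname, count in frag_counts.items():
        gene = genes[gname]
        tx = gene.transcript_sequence(genome)
        coords = gene.transcript_positions()
        flen = min(fragment_len, len(tx))
        for _ in range(count):
            fid += 1
            start = int(rng.integers(0, len(tx) - flen + 1))
            frag = list(tx[start:start + flen])
            # per-molecule editing state
            for k in range(flen):
                pe = edit_by_pos.get(coords[start + k])
                if pe is not None and rng.random() < pe.efficiency:
                    base = pe.alt_base
                    if gene.strand == "-":
                        base = _COMPLEMENT[base]
                    frag[k] = base
            # substitution errors
            if error_rate > 0:
                for k in range(flen):
                    if rng.random() < error_rate:
                        frag[k] = rng.choice([b for b in "ACGT" if b != frag[k]])
            frag = "".join(frag)
            rl = min(read_len, flen)
            r1 = frag[:rl]
            r2 = revcomp(frag[-rl:])
            reads.append(Read(id=f"frag{fid}/1", bases=r1, mate=1, fragment_id=f"frag{fid}"))
            reads.append(Read(id=f"frag{fid}/2", bases=r2, mate=2, fragment_id=f"frag{fid}"))
    truth = SimulationTruth(
        rng_seed=seed,
        genes=list(annotation),
        expression_rates=dict(expression_rates),
        fragment_counts=frag_counts,
        edits=list(edit_by_pos.values()),
    )
    return reads, truth


def simulate_srna(
    genome: Plastome,
    footprints: Sequence[tuple[Interval, int]] = (),
    background_genes: Sequence[GeneModel] = (),
    background_depth: int = 3,
    seed: int = 0,
):
    """Small-RNA reads: per footprint, ``depth`` short (20-24 nt) reads
    sharing the footprint's core sequence with +/-2 nt end jitter; plus
    31-35 nt background fragments tiled across the background genes.

    Footprints are given as (interval, depth) with the interval on the plus
    strand; the core sequence is the genomic sequence of the interval.

    Returns (reads, truth).
    """
    from .mapping import Read

    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    planted: list[PlantedFootprint] = []
    rid = 0
    n = len(genome)
    for iv, depth in footprints:
        iv = iv if isinstance(iv, Interval) else Interval(*iv)
        core = genome.fetch(iv.start, iv.end)
        planted.append(PlantedFootprint(iv.start, iv.end, "+", core, int(depth)))
        # protected termini are sharply defined: jitter concentrates at zero,
        # so the exact core is always the modal read sequence
        jitter_p = [0.1, 0.15, 0.5, 0.15, 0.1]
        for _ in range(depth):
            jl = int(rng.choice([-2, -1, 0, 1, 2], p=jitter_p))
            jr = int(rng.choice([-2, -1, 0, 1, 2], p=jitter_p))
            s = max(1, iv.start + jl)
            e = min(n, iv.end + jr)
            while e - s + 1 > 24:
                e -= 1
            while e - s + 1 < 20:
                s = max(1, s - 1)
                if e - s + 1 < 20:
                    e = min(n, e + 1)
            rid += 1
            reads.append(Read(id=f"srna{rid}", bases=genome.fetch(s, e)))
    n_short = len(reads)
    for g in background_genes:
        span = g.span
        step = 20
        for start in range(span.start, span.end - 35 + 2, step):
            L = int(rng.integers(31, 36))
            end = min(start + L - 1, n)
            seq = genome.fetch(start, end)
            if g.strand == "-":
                seq = revcomp(seq)
            for _ in range(background_depth):
                rid += 1
                reads.append(Read(id=f"srna{rid}", bases=seq))
    truth = SimulationTruth(
        rng_seed=seed,
        footprints=planted,
        n_short_reads=n_short,
        n_long_reads=len(reads) - n_short,
    )
    return reads, truth
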