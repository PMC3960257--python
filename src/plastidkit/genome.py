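"""Plastome model: sequence, quadripartite partition, gene annotations and
static sequence accounting (GC content, gene counts, introns, codon usage,
coordinate transforms).

Coordinate convention: 1-based inclusive intervals throughout, matching the
printed tables of plastid genome reports.  Conversion to 0-based half-open
happens only at the GFF3/SAM/BED boundary (see :mod:`plastidkit.io`).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .exceptions import (
    AmbiguousBaseWarning,
    AmbiguousStructure,
    DanglingDuplicateLink,
    EmptyInterval,
    LengthNotMultipleOfThree,
    NoInvertedRepeat,
    PositionOutOfGene,
)

VALID_BASES = frozenset("ACGTN")

#: NCBI translation table 11 (bacterial / archaeal / plant plastid), the code
#: used for all plastid CDS translation in this package.
PLASTID_CODON_TABLE = CodonTable.unambiguous_rna_by_id[11]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T")


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive genomic interval.  ``start > end`` denotes an interval
    that wraps through the circular origin."""

    start: int
    end: int

    def length(self, genome_length: int | None = None) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("wrapping interval needs the genome length")
        return (genome_length - self.start + 1) + self.end

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def overlap(self, other: "Interval") -> int:
        """Overlap in bp with another non-wrapping interval."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class Plastome:
    """A chloroplast genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("empty genome sequence")
        if set(seq) - VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise ValueError(f"invalid bases in genome: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval; wraps the origin when
        the genome is circular and ``start > end``."""
        n = len(self.sequence)
        if start > end:
            if not self.circular:
                raise ValueError("wrapping fetch on a linear genome")
            return self.sequence[start - 1:] + self.sequence[:end]
        if start < 1 or end > n:
            raise ValueError(f"interval ({start},{end}) outside genome of length {n}")
        return self.sequence[start - 1:end]

    def base(self, pos: int) -> str:
        return self.sequence[(pos - 1) % len(self.sequence)]


@dataclass(frozen=True)
class RegionPartition:
    """Quadripartite partition: LSC, IRb, SSC, IRa (1-based inclusive)."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval

    def lengths(self, genome_length: int | None = None) -> tuple[int, int, int, int]:
        return (
            self.lsc.length(genome_length),
            self.irb.length(genome_length),
            self.ssc.length(genome_length),
            self.ira.length(genome_length),
        )

    def region_of(self, pos: int) -> str:
        if self.lsc.contains(pos):
            return "LSC"
        if self.ssc.contains(pos):
            return "SSC"
        return "IR"


@dataclass
class GeneModel:
    """A stranded, possibly multi-exon, possibly trans-spliced gene.

    Exons are listed in transcript (5'→3') order.  For trans-spliced genes the
    first inter-exon junction is the trans junction (the downstream exons form
    one contiguous part); that junction is never reported as an intron.
    ``exon_strands`` overrides the gene strand per exon for trans-spliced genes
    whose parts lie on different strands.
    """

    name: str
    type: str  # CDS | tRNA | rRNA
    strand: str  # + | -
    exons: list[Interval]
    trans_spliced: bool = False
    ir_copy_of: str | None = None
    region: str | None = None  # LSC | SSC | IR
    pseudo: bool = False
    exon_strands: list[str] | None = None

    def __post_init__(self):
        if self.type not in {"CDS", "tRNA", "rRNA"}:
            raise ValueError(f"unknown gene type {self.type!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = [e if isinstance(e, Interval) else Interval(*e) for e in self.exons]

    def strand_of_exon(self, i: int) -> str:
        if self.exon_strands is not None:
            return self.exon_strands[i]
        return self.strand

    @property
    def coding_length(self) -> int:
        return sum(e.length() for e in self.exons)

    @property
    def span(self) -> Interval:
        return Interval(min(e.start for e in self.exons), max(e.end for e in self.exons))

    def transcript_sequence(self, genome: Plastome) -> str:
        """Spliced transcript-strand DNA sequence (exons concatenated in
        transcript order, minus-strand exons reverse-complemented)."""
        parts = []
        for i, e in enumerate(self.exons):
            s = genome.fetch(e.start, e.end)
            if self.strand_of_exon(i) == "-":
                s = revcomp(s)
            parts.append(s)
        return "".join(parts)

    def transcript_positions(self) -> list[int]:
        """Genomic coordinate of every transcript position, in transcript order."""
        coords: list[int] = []
        for i, e in enumerate(self.exons):
            rng = range(e.start, e.end + 1)
            if self.strand_of_exon(i) == "-":
                rng = range(e.end, e.start - 1, -1)
            coords.extend(rng)
        return coords


# ---------------------------------------------------------------------------
# Quadripartite structure detection
# ---------------------------------------------------------------------------


def _maximal_rc_pairs(seq: str, min_length: int) -> list[tuple[int, int, int]]:
    """All maximal (i, j, l) with seq[i:i+l] == revcomp(seq[j:j+l]), 0-based,
    canonicalized to i <= j with distinct copies.  Seed-and-extend with a
    left-maximality guard so each maximal pair is extended exactly once."""
    n = len(seq)
    k = min(min_length, 32)
    if n < k:
        return []
    rc = revcomp(seq)
    index: dict[str, list[int]] = {}
    for j in range(n - k + 1):
        index.setdefault(rc[j:j + k], []).append(j)
    seen: set[tuple[int, int, int]] = set()
    out: list[tuple[int, int, int]] = []
    for i in range(n - k + 1):
        hits = index.get(seq[i:i + k])
        if not hits:
            continue
        for j in hits:
            if i > 0 and j > 0 and seq[i - 1] == rc[j - 1]:
                continue  # interior seed of a longer match
            l = k
            while i + l < n and j + l < n and seq[i + l] == rc[j + l]:
                l += 1
            if l < min_length:
                continue
            # map rc-space start j back to genome coordinates
            g2 = n - (j + l)
            a, b = min(i, g2), max(i, g2)
            if a == b:
                continue  # a palindrome matching itself is not a repeat pair
            key = (a, b, l)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def detect_quadripartite(genome: Plastome, min_ir_length: int = 1000) -> RegionPartition:
    """Partition the genome into LSC / IRb / SSC / IRa from its longest pair of
    disjoint, exactly reverse-complementary maximal segments.

    Labels follow the canonical plastome map orientation: the longer
    single-copy region is the LSC and the IR that follows it (circularly) is
    IRb.  The search is over the linear sequence; an IR copy spanning the
    origin is not detected.

    Raises
    ------
    NoInvertedRepeat
        when no qualifying pair of length >= ``min_ir_length`` exists.
    AmbiguousStructure
        when two distinct candidate pairs tie for the maximum length.
    """
    n = len(genome)
    if n < 2 * min_ir_length:
        raise NoInvertedRepeat(
            f"genome of {n} bp cannot hold two IR copies of >= {min_ir_length} bp"
        )
    pairs = [
        (i, j, l)
        for (i, j, l) in _maximal_rc_pairs(genome.sequence, min_ir_length)
        if i + l <= j  # disjoint copies
    ]
    if not pairs:
        raise NoInvertedRepeat(f"no inverted repeat of >= {min_ir_length} bp found")
    best = max(l for (_, _, l) in pairs)
    winners = sorted({(i, j) for (i, j, l) in pairs if l == best})
    if len(winners) > 1:
        raise AmbiguousStructure(
            f"{len(winners)} non-nested inverted-repeat pairs tie at {best} bp"
        )
    i, j = winners[0]
    ir1 = Interval(i + 1, i + best)
    ir2 = Interval(j + 1, j + best)
    inner = Interval(ir1.end + 1, ir2.start - 1)  # between the two copies
    # outer single-copy region wraps through the origin when both flanks exist
    head_len = ir1.start - 1
    tail_len = n - ir2.end
    if tail_len and head_len:
        outer = Interval(ir2.end + 1, ir1.start - 1)  # wrapping
    elif tail_len:
        outer = Interval(ir2.end + 1, n)
    else:
        outer = Interval(1, max(ir1.start - 1, 1)) if head_len else Interval(1, 0)
    if inner.end < inner.start:
        raise NoInvertedRepeat("inverted-repeat copies are adjacent; no single-copy region")
    if head_len + tail_len == 0:
        raise NoInvertedRepeat("no single-copy region outside the inverted repeats")
    inner_len = inner.length(n)
    outer_len = outer.length(n)
    if outer_len >= inner_len:
        lsc, ssc = outer, inner
        irb, ira = ir1, ir2  # circular order: ... outer, ir1, inner, ir2 ...
    else:
        lsc, ssc = inner, outer
        irb, ira = ir2, ir1
    return RegionPartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira)


def region_lengths_total(partition: RegionPartition, genome_length: int | None = None) -> int:
    """LSC + SSC + 2xIR; equals the genome length for a valid partition."""
    l, b, s, a = partition.lengths(genome_length)
    if b != a:
        raise ValueError(f"IR copies differ in length ({b} vs {a})")
    return l + b + s + a


def gc_content(genome: Plastome, interval: Interval | None = None) -> float:
    """(#G + #C) / (#A + #C + #G + #T) over the interval (N excluded from the
    denominator); whole genome when ``interval`` is omitted."""
    seq = genome.sequence if interval is None else genome.fetch(interval.start, interval.end)
    counts = Counter(seq)
    informative = sum(counts[b] for b in "ACGT")
    if informative == 0:
        raise EmptyInterval("interval has no informative (non-N) bases")
    return (counts["G"] + counts["C"]) / informative


# ---------------------------------------------------------------------------
# Gene accounting
# ---------------------------------------------------------------------------


def unique_gene_accounting(annotation: Sequence[GeneModel]) -> dict:
    """Count unique genes: records linked by ``ir_copy_of`` count once.

    Returns ``{"unique_total": int, "by_type": {type: int}, "ir_duplicated": int}``.
    """
    if not annotation:
        raise ValueError("empty annotation")
    names = {g.name for g in annotation}
    by_type: Counter = Counter()
    duplicated = 0
    for g in annotation:
        if g.ir_copy_of is not None:
            if g.ir_copy_of not in names:
                raise DanglingDuplicateLink(
                    f"{g.name}: ir_copy_of {g.ir_copy_of!r} not in annotation"
                )
            duplicated += 1
            continue
        by_type[g.type] += 1
    return {
        "unique_total": sum(by_type.values()),
        "by_type": dict(by_type),
        "ir_duplicated": duplicated,
    }


def intron_catalog(annotation: Sequence[GeneModel]) -> dict:
    """Per-gene exon and intron lengths in transcript order, plus the global
    largest intron and its host gene.

    The gap at a trans-splicing junction (the first junction of a
    trans-spliced gene) is not an intron and is reported as ``None``.
    """
    rows = []
    largest = (0, None)  # (length, gene)
    for g in annotation:
        exon_lengths = [e.length() for e in g.exons]
        introns: list[int | None] = []
        for i in range(len(g.exons) - 1):
            if g.trans_spliced and i == 0:
                introns.append(None)
                continue
            a, b = g.exons[i], g.exons[i + 1]
            if b.start > a.end:
                gap = b.start - a.end - 1
            else:
                gap = a.start - b.end - 1
            introns.append(gap)
            if gap > largest[0]:
                largest = (gap, g.name)
        rows.append(
            {
                "gene": g.name,
                "region": g.region,
                "exon_lengths": exon_lengths,
                "intron_lengths": introns,
                "coding_length": sum(exon_lengths),
            }
        )
    return {
        "genes": rows,
        "largest_intron": largest[0],
        "largest_intron_gene": largest[1],
    }


@dataclass
class CodonUsageTable:
    """Codon counts over all unique protein-coding genes (RNA alphabet)."""

    counts: dict[str, int]
    anticodon_map: dict[str, str | None] = field(default_factory=dict)
    amino_acid_totals: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def amino_acid_total(self, aa: str) -> int:
        return self.amino_acid_totals.get(aa, 0)


def translate_codon(codon_rna: str) -> str:
    """One-letter amino acid for an RNA codon under translation table 11;
    ``*`` for stop codons."""
    if codon_rna in PLASTID_CODON_TABLE.stop_codons:
        return "*"
    return PLASTID_CODON_TABLE.forward_table[codon_rna]


def aggregate_amino_acid_totals(counts: Mapping[str, int]) -> dict[str, int]:
    totals: Counter = Counter()
    for codon, c in counts.items():
        totals[translate_codon(codon)] += c
    return dict(totals)


def _anticodon_map(annotation: Iterable[GeneModel]) -> dict[str, str | None]:
    """Codon -> tRNA name from tRNA gene names of the form trnX-ACG /
    trnX(ACG); the recognized codon is the reverse complement of the
    anticodon."""
    amap: dict[str, str | None] = {}
    for g in annotation:
        if g.type != "tRNA" or g.ir_copy_of is not None:
            continue
        name = g.name.replace("(", "-").replace(")", "")
        if "-" not in name:
            continue
        anticodon = name.rsplit("-", 1)[1].strip()
        if len(anticodon) != 3 or set(to_dna(anticodon)) - set("ACGT"):
            continue
        codon = to_rna(revcomp(to_dna(anticodon)))
        amap[codon] = g.name
    return amap


def codon_usage(annotation: Sequence[GeneModel], genome: Plastome) -> CodonUsageTable:
    """Codon usage over unique CDS genes (IR duplicates counted once),
    aggregated under translation table 11.

    Minus-strand genes are reverse-complemented and trans-spliced parts are
    concatenated in transcript order before codon extraction.  A CDS whose
    length is not a multiple of 3 triggers a warning and trailing bases are
    truncated; codons containing N are skipped with a warning.
    """
    counts: Counter = Counter()
    for g in annotation:
        if g.type != "CDS" or g.ir_copy_of is not None or g.pseudo:
            continue
        cds = g.transcript_sequence(genome)
        if len(cds) % 3:
            warnings.warn(
                f"{g.name}: CDS length {len(cds)} not a multiple of 3; truncating",
                LengthNotMultipleOfThree,
                stacklevel=2,
            )
            cds = cds[: len(cds) - len(cds) % 3]
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            if "N" in codon:
                warnings.warn(
                    f"{g.name}: skipping ambiguous codon {codon} at {i + 1}",
                    AmbiguousBaseWarning,
                    stacklevel=2,
                )
                continue
            counts[to_rna(codon)] += 1
    return CodonUsageTable(
        counts=dict(counts),
        anticodon_map=_anticodon_map(annotation),
        amino_acid_totals=aggregate_amino_acid_totals(counts),
    )


def codon_usage_from_counts(counts: Mapping[str, int]) -> CodonUsageTable:
    """Build a usage table directly from per-codon counts (RNA alphabet)."""
    counts = {to_rna(c): int(n) for c, n in counts.items()}
    return CodonUsageTable(
        counts=counts, amino_acid_totals=aggregate_amino_acid_totals(counts)
    )


# ---------------------------------------------------------------------------
# Gene-space / genome-space coordinate transforms
# ---------------------------------------------------------------------------


def gene_position_to_codon(gene: GeneModel, position_in_gene: int) -> dict:
    """Map a 1-based transcript position of a CDS gene to its codon index,
    offset within the codon, and genomic coordinate."""
    if gene.type != "CDS":
        raise PositionOutOfGene(f"{gene.name} is not a CDS gene")
    L = gene.coding_length
    if not 1 <= position_in_gene <= L:
        raise PositionOutOfGene(
            f"position {position_in_gene} outside {gene.name} (length {L})"
        )
    codon_index = (position_in_gene + 2) // 3
    offset = (position_in_gene - 1) % 3 + 1
    genomic = gene.transcript_positions()[position_in_gene - 1]
    return {
        "codon_index": codon_index,
        "offset_in_codon": offset,
        "genomic_position": genomic,
    }


def genomic_to_gene_position(gene: GeneModel, genomic_position: int) -> int:
    """Inverse of :func:`gene_position_to_codon`'s coordinate map: the 1-based
    transcript position of a genomic coordinate inside the gene's exons."""
    coords = gene.transcript_positions()
    try:
        return coords.index(genomic_position) + 1
    except ValueError:
        raise PositionOutOfGene(
            f"genomic position {genomic_position} not in exons of {gene.name}"
        ) from None
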