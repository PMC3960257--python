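"""Plastid small-RNA footprint discovery.

Short (20-24 nt) RNAs that accumulate where an RNA-binding protein (e.g. a
PPR protein) protects a transcript terminus from exonucleolytic decay leave
sharply localized read stacks.  Footprint loci are called by comparing the
per-base coverage of the 20-24 nt size class with the coverage of longer
(>30 nt) fragments, which trace abundant RNA species rather than protected
termini: a locus is a maximal run of positions where short-read coverage
reaches ``min_reads`` and exceeds the long-read background by
``enrichment_ratio``-fold (with a +1 pseudo-count so zero background never
divides by zero).  Runs closer than ``merge_gap`` are merged, per strand.

The core sequence of a locus is its most abundant unique supporting read;
ortholog matching across species uses global-alignment identity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .exceptions import EmptyLocus
from .genome import GeneModel, Interval
from .mapping import Alignment, Read

SHORT_RANGE = (20, 24)
LONG_MIN = 31


@dataclass
class StrandCoverage:
    """Per-base read coverage, split by mapped strand (1-based position p is
    index p-1)."""

    plus: np.ndarray
    minus: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.plus + self.minus

    def on(self, strand: str) -> np.ndarray:
        return self.plus if strand == "+" else self.minus


@dataclass
class SRNALocus:
    """An interval enriched in 20-24 nt reads."""

    start: int
    end: int
    strand: str
    core_sequence: str | None = None
    core_length: int | None = None
    read_count: int = 0
    location_class: str | None = None
    ir_duplicate_of: Interval | None = None

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def size_stratified_coverage(
    alignments: Sequence[Alignment],
    reads: Sequence[Read] | dict[str, Read],
    genome_length: int,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_min: int = LONG_MIN,
) -> tuple[StrandCoverage, StrandCoverage]:
    """Per-base coverage vectors of the short (20-24 nt) and long (>30 nt)
    size classes.  Multi-mapped reads contribute at every placement."""
    lookup = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    short = StrandCoverage(
        np.zeros(genome_length, dtype=np.int64), np.zeros(genome_length, dtype=np.int64)
    )
    long = StrandCoverage(
        np.zeros(genome_length, dtype=np.int64), np.zeros(genome_length, dtype=np.int64)
    )
    for aln in alignments:
        L = len(lookup[aln.read_id])
        if short_range[0] <= L <= short_range[1]:
            cov = short
        elif L >= long_min:
            cov = long
        else:
            continue
        vec = cov.plus if aln.strand == "+" else cov.minus
        lo = aln.start - 1
        hi = min(lo + L, genome_length)
        vec[lo:hi] += 1
        if lo + L > genome_length:  # circular wrap
            vec[: lo + L - genome_length] += 1
    return short, long


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as 0-based [start, end] inclusive pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def call_srna_loci(
    short_cov: StrandCoverage,
    long_cov: StrandCoverage,
    min_reads: int = 20,
    enrichment_ratio: float = 5.0,
    merge_gap: int = 10,
    alignments: Sequence[Alignment] | None = None,
    reads: Sequence[Read] | dict[str, Read] | None = None,
) -> list[SRNALocus]:
    """Call footprint loci per strand from size-stratified coverage.

    When ``alignments`` and ``reads`` are supplied, each locus is annotated
    with its supporting short-read count and core sequence.
    """
    loci: list[SRNALocus] = []
    for strand in "+-":
        s = short_cov.on(strand)
        l = long_cov.on(strand)
        mask = (s >= min_reads) & (s / (l + 1.0) >= enrichment_ratio)
        runs = _runs(mask)
        merged: list[list[int]] = []
        for a, b in runs:
            if merged and a - merged[-1][1] - 1 < merge_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            loci.append(SRNALocus(start=a + 1, end=b + 1, strand=strand))
    loci.sort(key=lambda x: (x.start, x.strand))
    if alignments is not None and reads is not None:
        for locus in loci:
            seq, count, strand = core_sequence(locus, alignments, reads)
            n_support = _supporting(locus, alignments, reads)
            locus.core_sequence = seq
            locus.core_length = len(seq)
            locus.read_count = n_support
            locus.strand = strand
    return loci


def _supporting(
    locus: SRNALocus,
    alignments: Sequence[Alignment],
    reads: Sequence[Read] | dict[str, Read],
    short_range: tuple[int, int] = SHORT_RANGE,
) -> int:
    lookup = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    n = 0
    for aln in alignments:
        L = len(lookup[aln.read_id])
        if not short_range[0] <= L <= short_range[1]:
            continue
        if aln.start <= locus.end and aln.start + L - 1 >= locus.start:
            n += 1
    return n


def core_sequence(
    locus: SRNALocus,
    alignments: Sequence[Alignment],
    reads: Sequence[Read] | dict[str, Read],
    short_range: tuple[int, int] = SHORT_RANGE,
) -> tuple[str, int, str]:
    """Most abundant unique short-read sequence overlapping the locus.

    Ties break lexicographically; the returned strand is the majority mapped
    strand of the overlapping reads (``+`` on a tie).
    """
    lookup = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    seqs: Counter = Counter()
    strands: Counter = Counter()
    for aln in alignments:
        read = lookup[aln.read_id]
        L = len(read)
        if not short_range[0] <= L <= short_range[1]:
            continue
        if aln.start <= locus.end and aln.start + L - 1 >= locus.start:
            seqs[read.bases] += 1
            strands[aln.strand] += 1
    if not seqs:
        raise EmptyLocus(f"no supporting reads at {locus.start}-{locus.end}")
    best = max(seqs.values())
    seq = min(s for s, c in seqs.items() if c == best)
    strand = "+" if strands["+"] >= strands["-"] else "-"
    return seq, best, strand


def classify_locus_location(
    locus: SRNALocus,
    annotation: Sequence[GeneModel],
    window_5prime: tuple[int, int] = (-150, 50),
    end_window: int = 100,
) -> str:
    """Genomic context class of a locus.

    ``CDS`` when the midpoint lies in an exon, ``intron`` when in an intron;
    otherwise intergenic, sub-classed ``intergenic_5prime`` when the midpoint
    lies within ``window_5prime`` (signed, transcript direction) of a
    same-strand start codon, ``intergenic_3prime`` when within ``end_window``
    of a stop codon, else ``intergenic_other``.
    """
    mid = locus.midpoint
    for g in annotation:
        if any(e.contains(mid) for e in g.exons):
            return "CDS"
        for i in range(len(g.exons) - 1):
            if g.trans_spliced and i == 0:
                continue
            a, b = g.exons[i], g.exons[i + 1]
            lo, hi = (a.end + 1, b.start - 1) if b.start > a.end else (b.end + 1, a.start - 1)
            if lo <= mid <= hi:
                return "intron"
    for g in annotation:
        if g.strand != locus.strand:
            continue
        span = g.span
        start_codon = span.start if g.strand == "+" else span.end
        offset = mid - start_codon if g.strand == "+" else start_codon - mid
        if window_5prime[0] <= offset <= window_5prime[1]:
            return "intergenic_5prime"
    for g in annotation:
        if g.strand != locus.strand:
            continue
        span = g.span
        stop_codon = span.end if g.strand == "+" else span.start
        if abs(mid - stop_codon) <= end_window:
            return "intergenic_3prime"
    return "intergenic_other"


def alignment_identity(a: str, b: str) -> float:
    """Matches / alignment length under unit-cost global (Needleman-Wunsch)
    alignment."""
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches = 0
    length = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            k = int(num)
            num = ""
            length += k
            if ch == "=":
                matches += k
    return matches / length if length else 0.0


def ortholog_match(
    query_srnas: Mapping[str, str],
    reference_srnas: Mapping[str, str],
    min_identity: float = 0.90,
) -> list[tuple[str, str, float]]:
    """Best-identity reference match per query small RNA.

    Returns (query, reference, identity) for every query whose best
    global-alignment identity against the reference set reaches
    ``min_identity``.
    """
    out = []
    for qname, qseq in query_srnas.items():
        best: tuple[float, str] | None = None
        for rname, rseq in reference_srnas.items():
            ident = alignment_identity(qseq, rseq)
            if best is None or ident > best[0]:
                best = (ident, rname)
        if best is not None and best[0] >= min_identity:
            out.append((qname, best[1], best[0]))
    return out
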