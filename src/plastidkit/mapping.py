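"""Exhaustive mismatch-bounded ungapped read mapping and pileup.

The mapper scans every placement of a read on both strands of the genome
(with circular wrap when the genome is circular) and reports the
equally-best placements under a Hamming-distance bound.  This is deliberate
desk-scale plumbing: substitution-level evidence is all the downstream
analyses (editing, FPKM, small-RNA footprints) need, and an exhaustive scan
is exactly verifiable against a naive oracle.  N in either the read or the
genome counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import Plastome, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
BASES = "ACGT"


_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_LUT[ord(_b)] = _c


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Read:
    """A sequencing read.  ``mate`` is 1/2 for paired ends, None for
    single-end; ``fragment_id`` groups the two mates of one fragment."""

    id: str
    bases: str
    mate: int | None = None
    fragment_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Alignment:
    """One placement of a read.  ``start`` is the 1-based leftmost genome
    coordinate of the placement (which may wrap the origin on a circular
    genome); ``multi_hits`` is the number of equally-best placements the read
    has overall."""

    read_id: str
    start: int
    strand: str
    mismatches: int
    multi_hits: int = 1
    length: int = 0

    @property
    def end(self) -> int:
        """1-based inclusive end, not wrapped (may exceed the genome length)."""
        return self.start + self.length - 1


@dataclass
class MappingResult:
    alignments: list[Alignment]
    unmapped: list[str] = field(default_factory=list)


class GenomeIndex:
    """Encoded genome with the circular extension pre-computed."""

    def __init__(self, genome: Plastome, max_read_length: int = 512):
        self.genome = genome
        self.n = len(genome)
        ext = genome.sequence + (
            genome.sequence[: max_read_length - 1] if genome.circular else ""
        )
        self.encoded = _encode(ext)

    def mismatch_profile(self, read_bases: str) -> np.ndarray:
        """Hamming distance of the read against every placement (0-based
        start positions 0..n_pos-1)."""
        r = _encode(read_bases)
        L = len(r)
        n_pos = self.n if self.genome.circular else self.n - L + 1
        if n_pos <= 0:
            return np.empty(0, dtype=np.int32)
        win = np.lib.stride_tricks.sliding_window_view(self.encoded[: n_pos + L - 1], L)
        mism = ((win != r) | (win == 4) | (r == 4)).sum(axis=1)
        return mism.astype(np.int32)


def map_reads(
    reads: Sequence[Read],
    genome: Plastome,
    max_mismatch: int = 2,
    report_multi: bool = True,
    index: GenomeIndex | None = None,
) -> MappingResult:
    """Map reads by exhaustive ungapped search on both strands.

    Each read is reported at all equally-best placements when
    ``report_multi``, otherwise at the single deterministic placement with the
    lowest coordinate (plus strand first on ties).  Reads whose best placement
    exceeds ``max_mismatch`` are listed in ``unmapped``.
    """
    if index is None:
        max_len = max((len(r) for r in reads), default=0)
        index = GenomeIndex(genome, max_read_length=max(max_len, 1))
    out: list[Alignment] = []
    unmapped: list[str] = []
    for read in reads:
        if len(read) < 15 or len(read) > len(genome):
            unmapped.append(read.id)
            continue
        placements: list[tuple[int, str, int]] = []  # (start0, strand, mism)
        best = max_mismatch + 1
        for strand, bases in (("+", read.bases), ("-", revcomp(read.bases))):
            prof = index.mismatch_profile(bases)
            if prof.size == 0:
                continue
            m = int(prof.min())
            if m < best:
                best = m
                placements = []
            if m <= max_mismatch and m == best:
                for p in np.flatnonzero(prof == m):
                    placements.append((int(p), strand, m))
        if best > max_mismatch or not placements:
            unmapped.append(read.id)
            continue
        placements.sort(key=lambda t: (t[0], t[1]))
        k = len(placements)
        chosen = placements if report_multi else placements[:1]
        for p, strand, m in chosen:
            out.append(
                Alignment(
                    read_id=read.id,
                    start=p + 1,
                    strand=strand,
                    mismatches=m,
                    multi_hits=k,
                    length=len(read),
                )
            )
    return MappingResult(alignments=out, unmapped=unmapped)


@dataclass(frozen=True)
class PileupColumn:
    """Per-position, per-strand base tallies in genome-strand space."""

    position: int
    counts: dict  # base -> (plus_count, minus_count)

    def total(self) -> int:
        return sum(p + m for p, m in self.counts.values())

    def base_total(self, base: str) -> int:
        p, m = self.counts.get(base, (0, 0))
        return p + m


class Pileup:
    """Dense per-position, per-strand base counts over the genome.

    Minus-strand read bases are complemented into genome-strand space, so a
    column's counts always describe the forward genome strand; the strand
    split records which strand the supporting reads mapped to.
    """

    def __init__(self, genome_length: int, circular: bool = True):
        self.n = genome_length
        self.circular = circular
        # axes: strand (0 = plus, 1 = minus), base (ACGTN), position
        self.counts = np.zeros((2, 5, genome_length), dtype=np.int32)

    def add_alignment(self, aln: Alignment, read: Read) -> None:
        bases = read.bases if aln.strand == "+" else revcomp(read.bases)
        si = 0 if aln.strand == "+" else 1
        for k, b in enumerate(bases):
            pos0 = aln.start - 1 + k
            if pos0 >= self.n:
                if not self.circular:
                    break
                pos0 %= self.n
            self.counts[si, _CODE.get(b, 4), pos0] += 1

    def column(self, position: int) -> PileupColumn:
        pos0 = (position - 1) % self.n
        return PileupColumn(
            position=position,
            counts={
                b: (int(self.counts[0, i, pos0]), int(self.counts[1, i, pos0]))
                for i, b in enumerate("ACGTN")
                if self.counts[:, i, pos0].any()
            },
        )

    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 1))

    def covered_positions(self) -> np.ndarray:
        """1-based positions with at least one aligned base."""
        return np.flatnonzero(self.coverage()) + 1


def build_pileup(
    alignments: Iterable[Alignment],
    reads: Sequence[Read] | dict[str, Read],
    genome: Plastome,
) -> Pileup:
    """Accumulate per-position, per-strand base tallies from alignments."""
    lookup = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    pile = Pileup(len(genome), circular=genome.circular)
    for aln in alignments:
        pile.add_alignment(aln, lookup[aln.read_id])
    return pile


def filter_reads_by_length(
    reads: Sequence[Read], min_len: int, max_len: int
) -> tuple[list[Read], list[Read]]:
    """Order-preserving partition into (inside range, outside range)."""
    kept, rest = [], []
    for r in reads:
        (kept if min_len <= len(r) <= max_len else rest).append(r)
    return kept, rest
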