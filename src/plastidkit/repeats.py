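"""Maximal repeat survey: forward (direct), palindromic (reverse-complement)
and reverse (reversed, not complemented) exact maximal repeats, with an
expectation-based significance filter and annotation-aware location classes.

The significance statistic is the expected number of repeated pairs of the
observed length in a uniform-base random sequence of the same size,

    E(l, n) = (n - l + 1)(n - l) / 2 * 4^(-l)

per orientation.  It plays the role of the e-value threshold used by
REPuter-style surveys; exact reproduction of any particular tool's statistic
is not claimed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .genome import GeneModel, Interval, Plastome, RegionPartition, revcomp

SIZE_BINS = ("<25", "25-40", "41-80", ">80")


def repeat_e_value(length: int, genome_length: int) -> float:
    """Expected count of exact repeated pairs of this length under a uniform
    i.i.d. base model (one orientation)."""
    n, l = genome_length, length
    if l > n:
        return 0.0
    return (n - l + 1) * (n - l) / 2 * 4.0 ** (-l)


def size_bin(length: int) -> str:
    if length < 25:
        return "<25"
    if length <= 40:
        return "25-40"
    if length <= 80:
        return "41-80"
    return ">80"


@dataclass
class RepeatHit:
    """One maximal repeated pair.  ``pos1``/``pos2`` are 1-based start
    positions of the two copies, with ``pos1 <= pos2``."""

    orientation: str  # F | P | R
    length: int
    pos1: int
    pos2: int
    e_value: float
    location_class: str | None = None

    @property
    def size_bin(self) -> str:
        return size_bin(self.length)

    @property
    def copy1(self) -> Interval:
        return Interval(self.pos1, self.pos1 + self.length - 1)

    @property
    def copy2(self) -> Interval:
        return Interval(self.pos2, self.pos2 + self.length - 1)


def _maximal_pairs_vs(a: str, b: str, min_length: int) -> set[tuple[int, int, int]]:
    """Maximal matches (i, j, l) with a[i:i+l] == b[j:j+l], 0-based.  Seeds are
    extended only when not left-extendable, so each maximal pair is visited
    once."""
    k = min(min_length, 24)
    na, nb = len(a), len(b)
    if na < k or nb < k:
        return set()
    index: dict[str, list[int]] = {}
    for j in range(nb - k + 1):
        index.setdefault(b[j:j + k], []).append(j)
    out: set[tuple[int, int, int]] = set()
    for i in range(na - k + 1):
        hits = index.get(a[i:i + k])
        if not hits:
            continue
        for j in hits:
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue
            l = k
            while i + l < na and j + l < nb and a[i + l] == b[j + l]:
                l += 1
            if l >= min_length:
                out.add((i, j, l))
    return out


def find_maximal_repeats(
    genome: Plastome,
    min_length: int = 20,
    max_e_value: float = 1e-3,
    partition: RegionPartition | None = None,
    include_ir_self_match: bool = False,
) -> list[RepeatHit]:
    """Enumerate exact maximal repeats of all three orientations.

    Every returned pair is maximal (extending either end in its orientation
    breaks the match) and passes both the length and e-value filters.  When a
    quadripartite ``partition`` is supplied, the single giant palindromic hit
    formed by the IR pair itself is suppressed unless
    ``include_ir_self_match`` is set — a plastome repeat survey counts the
    small dispersed repeats, not the 20+ kb IR duplication.

    Output is deterministic, sorted by (length desc, pos1 asc, pos2 asc).
    """
    if min_length < 8:
        raise ValueError("min_length < 8 would enumerate a combinatorial number of hits")
    s = genome.sequence
    n = len(s)
    hits: list[RepeatHit] = []

    # forward: matches of the sequence against itself, excluding self-identity
    for i, j, l in _maximal_pairs_vs(s, s, min_length):
        if i >= j:
            continue  # keep one of each symmetric pair; drop i == j
        hits.append(RepeatHit("F", l, i + 1, j + 1, repeat_e_value(l, n)))

    # palindromic: matches against the reverse complement, mapped back
    seen: set[tuple[int, int, int]] = set()
    for i, j, l in _maximal_pairs_vs(s, revcomp(s), min_length):
        g2 = n - (j + l)  # 0-based start of copy 2 on the forward strand
        a, b = min(i, g2), max(i, g2)
        if a == b:
            continue  # a self-reverse-complementary segment is one copy, not a pair
        key = (a, b, l)
        if key not in seen:
            seen.add(key)
            hits.append(RepeatHit("P", l, a + 1, b + 1, repeat_e_value(l, n)))

    # reverse (reversed, not complemented)
    seen = set()
    for i, j, l in _maximal_pairs_vs(s, s[::-1], min_length):
        g2 = n - (j + l)
        a, b = min(i, g2), max(i, g2)
        if a == b:
            continue
        key = (a, b, l)
        if key not in seen:
            seen.add(key)
            hits.append(RepeatHit("R", l, a + 1, b + 1, repeat_e_value(l, n)))

    hits = [h for h in hits if h.e_value < max_e_value]
    if partition is not None and not include_ir_self_match:
        irb, ira = partition.irb, partition.ira
        hits = [
            h
            for h in hits
            if not (
                h.orientation == "P"
                and h.copy1 == Interval(min(irb.start, ira.start), min(irb.end, ira.end))
                and h.copy2 == Interval(max(irb.start, ira.start), max(irb.end, ira.end))
            )
        ]
    hits.sort(key=lambda h: (-h.length, h.pos1, h.pos2))
    return hits


def classify_repeat_location(
    hit: RepeatHit, annotation: Sequence[GeneModel]
) -> str:
    """Location class of the first copy: exonic (CDS), intronic, or
    intergenic, decided by majority overlap (ties favour CDS, then intron)."""
    iv = hit.copy1
    exonic = 0
    intronic = 0
    for g in annotation:
        for e in g.exons:
            exonic += iv.overlap(e)
        for i in range(len(g.exons) - 1):
            if g.trans_spliced and i == 0:
                continue
            a, b = g.exons[i], g.exons[i + 1]
            lo, hi = (a.end + 1, b.start - 1) if b.start > a.end else (b.end + 1, a.start - 1)
            if lo <= hi:
                intronic += iv.overlap(Interval(lo, hi))
        if exonic + intronic >= iv.length():
            break
    exonic = min(exonic, iv.length())
    intergenic = max(0, iv.length() - exonic - intronic)
    best = max(exonic, intronic, intergenic)
    if exonic == best:
        return "CDS"
    if intronic == best:
        return "intron"
    return "intergenic"


def summarize_repeats(hits: Sequence[RepeatHit]) -> dict:
    """Counts by orientation and by size bin; both partitions of the hit list."""
    by_orientation = Counter(h.orientation for h in hits)
    by_size = Counter(h.size_bin for h in hits)
    return {
        "total": len(hits),
        "by_orientation": {o: by_orientation.get(o, 0) for o in "FPR"},
        "by_size_bin": {b: by_size.get(b, 0) for b in SIZE_BINS},
    }
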