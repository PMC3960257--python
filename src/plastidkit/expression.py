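"""Per-gene fragment counting and FPKM expression profiling.

FPKM = fragments per kilobase of exonic length per million mapped fragments:

    FPKM_g = count_g / ((exonic_length_g / 1000) * (total_mapped / 10^6))

The denominator's library size counts fragments aligned anywhere on the
plastome, not only those assigned to genes.  A fragment is assigned to a gene
when the midpoint of its aligned span lies inside an exon; midpoint
assignment avoids double-counting fragments that straddle a gene boundary.
Under the default ``all`` multi-mapping policy a fragment whose equally-best
placements hit both copies of an IR-duplicated gene is counted once in each
copy, so the two copies receive (near-)equal FPKM rather than splitting it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .exceptions import EmptyLibrary, ZeroLengthGene
from .genome import GeneModel, Interval
from .mapping import Alignment, Read


@dataclass
class ExpressionRecord:
    gene: str
    locus: Interval
    fragment_count: float
    fpkm: float


def _fragment_key(read: Read) -> str:
    if read.fragment_id is not None:
        return read.fragment_id
    # mate-suffixed ids like frag7/1, frag7/2 collapse to frag7
    if read.mate is not None and "/" in read.id:
        return read.id.rsplit("/", 1)[0]
    return read.id


def fragment_placements(
    alignments: Sequence[Alignment], reads: Sequence[Read] | dict[str, Read]
) -> dict[str, list[Interval]]:
    """Collapse mate alignments into fragment placements.

    For each fragment, the placements of its first mate (or the read itself
    for single-end data) anchor the fragment; each anchor is paired with the
    closest placement of the other mate to form the fragment span.  Returns
    fragment id -> list of equally-best spans.
    """
    lookup = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    by_frag: dict[str, dict[int, list[Alignment]]] = defaultdict(lambda: defaultdict(list))
    for aln in alignments:
        read = lookup[aln.read_id]
        mate = read.mate or 1
        by_frag[_fragment_key(read)][mate].append(aln)
    spans: dict[str, list[Interval]] = {}
    for frag, mates in by_frag.items():
        anchor_mate = min(mates)
        others = mates.get(3 - anchor_mate, []) if anchor_mate in (1, 2) else []
        out = []
        for a in mates[anchor_mate]:
            lo, hi = a.start, a.end
            if others:
                b = min(others, key=lambda o: (abs(o.start - a.start), o.start))
                lo, hi = min(lo, b.start), max(hi, b.end)
            out.append(Interval(lo, hi))
        spans[frag] = sorted(set(out))
    return spans


def count_fragments(
    alignments: Sequence[Alignment],
    reads: Sequence[Read] | dict[str, Read],
    annotation: Sequence[GeneModel],
    multimap_policy: str = "all",
) -> dict[str, float]:
    """Fragments per gene by midpoint-in-exon assignment.

    ``multimap_policy``:
      * ``all`` (default) — every equally-best placement of a fragment counts
        in the gene it lands in (an IR-duplicated gene gets the fragment in
        both copies);
      * ``primary`` — only the lowest-coordinate placement counts.
    """
    if multimap_policy not in {"all", "primary"}:
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    counts: dict[str, float] = {g.name: 0.0 for g in annotation}
    for frag, placements in fragment_placements(alignments, reads).items():
        if multimap_policy == "primary":
            placements = placements[:1]
        hit_genes: set[str] = set()
        for span in placements:
            mid = (span.start + span.end) // 2
            for g in annotation:
                if any(e.contains(mid) for e in g.exons):
                    hit_genes.add(g.name)
        for name in hit_genes:
            counts[name] = counts.get(name, 0.0) + 1.0
    return counts


def fpkm(count: float, coding_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if coding_length_bp <= 0:
        raise ZeroLengthGene("gene has no exonic length")
    if total_mapped_fragments <= 0:
        raise EmptyLibrary("no mapped fragments in the library")
    return count / ((coding_length_bp / 1000.0) * (total_mapped_fragments / 1e6))


def profile_expression(
    alignments: Sequence[Alignment],
    reads: Sequence[Read] | dict[str, Read],
    annotation: Sequence[GeneModel],
    multimap_policy: str = "all",
) -> list[ExpressionRecord]:
    """Full per-gene expression table: fragment counts and FPKM.

    The library size is the number of distinct fragments with at least one
    placement anywhere on the plastome.
    """
    total = len(fragment_placements(alignments, reads))
    counts = count_fragments(alignments, reads, annotation, multimap_policy)
    records = []
    for g in annotation:
        c = counts.get(g.name, 0.0)
        records.append(
            ExpressionRecord(
                gene=g.name,
                locus=g.span,
                fragment_count=c,
                fpkm=fpkm(c, g.coding_length, total) if total else 0.0,
            )
        )
    return rank_genes(records)


def rank_genes(
    records: Sequence[ExpressionRecord], top_k: int | None = None
) -> list[ExpressionRecord]:
    """Records in descending FPKM order, ties broken by gene name."""
    ranked = sorted(records, key=lambda r: (-r.fpkm, r.gene))
    return ranked[:top_k] if top_k is not None else ranked
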