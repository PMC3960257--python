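"""RNA-editing detection from DNA-reference vs RNA-pileup comparison.

A site is called where RNA reads disagree with the (haploid organellar) DNA
reference: coverage must reach ``min_coverage`` and the most frequent
non-reference base must reach ``min_alt_fraction`` of all observed bases.
Bases are reported in the RNA alphabet (U, not T) and in transcript
orientation — for a minus-strand gene both reference and alternate bases are
complemented before reporting, and conversion labels like ``C-to-U`` are
therefore strand-resolved.

Editing efficiency at a site is the fraction of all observed reads that
carry the alternate base (the denominator is the full base column, not just
reference + alternate), reported as a percentage to one decimal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .exceptions import PositionNotInCDS, ZeroCoverage
from .genome import (
    GeneModel,
    Plastome,
    gene_position_to_codon,
    genomic_to_gene_position,
    to_rna,
    translate_codon,
)

_AA_NAMES = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "stop",
}

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class EditingSite:
    """One RNA-vs-DNA discordant position, in transcript orientation."""

    gene: str
    position_in_gene: int | None
    genomic_position: int
    ref_base: str  # RNA alphabet, transcript strand
    alt_base: str
    base_counts: dict[str, int]  # RNA alphabet, transcript strand
    efficiency: float  # percent
    conversion: str  # e.g. "C-to-U"
    codon_change: tuple[str, str] | None = None
    aa_change: tuple[str, str] | None = None
    synonymous: bool | None = None


def editing_efficiency(
    base_counts: Mapping[str, int], ref_base: str, alt_base: str
) -> float:
    """100 x alt_count / (sum of all observed base counts), to one decimal."""
    total = sum(base_counts.values())
    if total == 0:
        raise ZeroCoverage("no reads observed at site")
    return round(100.0 * base_counts.get(alt_base, 0) / total, 1)


def _gene_at(position: int, annotation: Sequence[GeneModel]) -> GeneModel | None:
    for g in annotation:
        if any(e.contains(position) for e in g.exons):
            return g
    return None


def _utr_label(position: int, annotation: Sequence[GeneModel], window: int = 300) -> str:
    """Label for a site outside any exon: nearest same-window gene end, else
    intergenic."""
    best: tuple[int, str] | None = None
    for g in annotation:
        span = g.span
        five = span.start if g.strand == "+" else span.end
        three = span.end if g.strand == "+" else span.start
        for anchor, side in ((three, "3' UTR"), (five, "5' UTR")):
            d = abs(position - anchor)
            if d <= window and (best is None or d < best[0]):
                best = (d, f"{g.name} {side}")
    return best[1] if best else "intergenic"


def call_editing_sites(
    pileup,
    genome: Plastome,
    annotation: Sequence[GeneModel],
    min_coverage: int = 5,
    min_alt_fraction: float = 0.1,
) -> list[EditingSite]:
    """Scan an RNA pileup against the DNA reference and emit editing sites.

    Thresholds default to permissive values (coverage >= 5, alternate
    fraction >= 0.1) because genuine plastid editing sites can be supported by
    as few as two reads at modest rates; both are configurable.
    """
    sites: list[EditingSite] = []
    for pos in pileup.covered_positions():
        pos = int(pos)
        col = pileup.column(pos)
        total = sum(p + m for b, (p, m) in col.counts.items() if b != "N")
        if total < min_coverage:
            continue
        ref_dna = genome.base(pos)
        by_base = {
            b: p + m for b, (p, m) in col.counts.items() if b != "N" and (p + m) > 0
        }
        alts = {b: c for b, c in by_base.items() if b != ref_dna}
        if not alts:
            continue
        alt_dna = max(alts, key=lambda b: (alts[b], b))
        if alts[alt_dna] / total < min_alt_fraction:
            continue
        gene = _gene_at(pos, annotation)
        if gene is not None and gene.strand == "-":
            tx = {_DNA_COMPLEMENT[b]: c for b, c in by_base.items()}
            ref_t, alt_t = _DNA_COMPLEMENT[ref_dna], _DNA_COMPLEMENT[alt_dna]
        else:
            tx, ref_t, alt_t = dict(by_base), ref_dna, alt_dna
        counts_rna = {to_rna(b): c for b, c in tx.items()}
        ref_rna, alt_rna = to_rna(ref_t), to_rna(alt_t)
        site = EditingSite(
            gene=gene.name if gene is not None else _utr_label(pos, annotation),
            position_in_gene=(
                genomic_to_gene_position(gene, pos) if gene is not None else None
            ),
            genomic_position=pos,
            ref_base=ref_rna,
            alt_base=alt_rna,
            base_counts=counts_rna,
            efficiency=editing_efficiency(counts_rna, ref_rna, alt_rna),
            conversion=f"{ref_rna}-to-{alt_rna}",
        )
        if gene is not None and gene.type == "CDS":
            site = annotate_codon_change(site, gene, genome)
        sites.append(site)
    return sites


def annotate_codon_change(
    site: EditingSite, gene: GeneModel, genome: Plastome
) -> EditingSite:
    """Fill in codon and amino-acid impact for a site inside a CDS gene.

    The reference codon is read from the genome through the exon structure;
    the alternate codon substitutes the edited base at the site's offset.
    Translation uses the plastid genetic code; stop codons are labelled
    ``stop``.
    """
    if gene.type != "CDS" or site.position_in_gene is None:
        raise PositionNotInCDS(f"site at {site.genomic_position} is not inside a CDS")
    info = gene_position_to_codon(gene, site.position_in_gene)
    cds = to_rna(gene.transcript_sequence(genome))
    ci, off = info["codon_index"], info["offset_in_codon"]
    ref_codon = cds[(ci - 1) * 3: ci * 3]
    alt_codon = ref_codon[: off - 1] + site.alt_base + ref_codon[off:]
    ref_aa = _AA_NAMES[translate_codon(ref_codon)]
    alt_aa = _AA_NAMES[translate_codon(alt_codon)]
    site.codon_change = (ref_codon, alt_codon)
    site.aa_change = (ref_aa, alt_aa)
    site.synonymous = ref_aa == alt_aa
    return site


def summarize_conversion_spectrum(sites: Sequence[EditingSite]) -> dict[str, int]:
    """Counts of sites by conversion label (transcript orientation)."""
    return dict(Counter(s.conversion for s in sites))


def confirm_predictions(
    predicted_sites: Sequence[int], called_sites: Sequence[EditingSite] | Sequence[int]
) -> dict[str, set[int]]:
    """Intersect predicted genomic positions with called sites.

    Returns disjoint sets ``confirmed`` / ``predicted_only`` / ``called_only``
    by exact genomic position.
    """
    called_pos = {
        s.genomic_position if isinstance(s, EditingSite) else int(s)
        for s in called_sites
    }
    predicted = set(int(p) for p in predicted_sites)
    return {
        "confirmed": predicted & called_pos,
        "predicted_only": predicted - called_pos,
        "called_only": called_pos - predicted,
    }
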