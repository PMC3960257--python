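"""RNA-editing calling, efficiency statistic and codon impact."""

import numpy as np
import pytest
from scipy import stats

import plastidkit as pk
from plastidkit import published as pub
from plastidkit.exceptions import PositionNotInCDS, ZeroCoverage


class TestEfficiency:
    @pytest.mark.parametrize(
        "counts,ref,alt,expected",
        [
            ({"U": 11, "C": 27}, "C", "U", 28.9),
            ({"C": 2, "U": 66}, "C", "U", 97.1),
            ({"A": 55, "U": 28}, "U", "A", 66.3),
            ({"C": 2, "U": 10, "G": 1}, "C", "U", 76.9),  # full-column denominator
            ({"U": 19}, "C", "U", 100.0),
        ],
    )
    def test_published_rates(self, counts, ref, alt, expected):
        assert pk.editing_efficiency(counts, ref, alt) == expected

    def test_zero_coverage_raises(self):
        with pytest.raises(ZeroCoverage):
            pk.editing_efficiency({}, "C", "U")

    def test_percentages_sum_to_100_over_all_bases(self):
        counts = {"C": 7, "U": 11, "G": 2}
        total = sum(
            pk.editing_efficiency(counts, "C", b) for b in counts
        )
        assert total == pytest.approx(100.0, abs=0.2)  # rounding only


def _pileup_with_column(genome, pos, base_counts):
    """A pileup with one populated column; counts are (plus, minus) pairs in
    genome-strand space, as build_pileup would record them."""
    pile = pk.Pileup(len(genome))
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    for base, (p, m) in base_counts.items():
        pile.counts[0, code[base], pos - 1] += p
        pile.counts[1, code[base], pos - 1] += m
    return pile


class TestCalling:
    def test_c_to_u_site_called_on_plus_strand_cds(self):
        genome = pk.Plastome(id="g", sequence="ATG" + "C" * 297, circular=False)
        gene = pk.GeneModel(name="matK", type="CDS", strand="+",
                            exons=[pk.Interval(1, 300)])
        pile = _pileup_with_column(genome, 10, {"C": (27, 0), "T": (11, 0)})
        sites = pk.call_editing_sites(pile, genome, [gene], 10, 0.1)
        (site,) = sites
        assert (site.ref_base, site.alt_base) == ("C", "U")
        assert site.conversion == "C-to-U"
        assert site.efficiency == 28.9
        assert site.position_in_gene == 10

    def test_no_alternate_no_site(self):
        genome = pk.Plastome(id="g", sequence="C" * 100, circular=False)
        pile = _pileup_with_column(genome, 10, {"C": (30, 0)})
        assert pk.call_editing_sites(pile, genome, [], 10, 0.1) == []

    def test_site_outside_genes_labelled(self):
        genome = pk.Plastome(id="g", sequence="C" * 400, circular=False)
        gene = pk.GeneModel(name="ndhJ", type="CDS", strand="+",
                            exons=[pk.Interval(1, 90)])
        pile = _pileup_with_column(genome, 100, {"C": (10, 0), "A": (9, 0)})
        (site,) = pk.call_editing_sites(pile, genome, [gene], 5, 0.1)
        assert site.gene == "ndhJ 3' UTR"
        assert site.position_in_gene is None
        assert site.codon_change is None

    def test_planted_edits_recovered_without_false_positives(self, annotated_genome):
        genome, _, genes, _ = annotated_genome
        single = [g for g in genes if len(g.exons) == 1 and g.ir_copy_of is None][:3]
        rates = {g.name: 2.0 for g in single}
        planted = [(g.transcript_positions()[50 + 17 * i], 0.9)
                   for i, g in enumerate(single)]
        reads, truth = pk.simulate_rnaseq(genome, single, rates,
                                          editing_sites=planted, n_fragments=600,
                                          read_len=50, fragment_len=150,
                                          error_rate=0.0, seed=12)
        res = pk.map_reads(reads, genome, 2)
        pile = pk.build_pileup(res.alignments, reads, genome)
        sites = pk.call_editing_sites(pile, genome, single, 5, 0.1)
        assert {s.genomic_position for s in sites} == {p for p, _ in planted}

    def test_planted_efficiency_inside_99pct_binomial_interval(self, annotated_genome):
        genome, _, genes, _ = annotated_genome
        single = [g for g in genes if len(g.exons) == 1 and g.ir_copy_of is None][:2]
        eff = 0.85
        planted = [(g.transcript_positions()[120], eff) for g in single]
        reads, _ = pk.simulate_rnaseq(genome, single, {g.name: 1.0 for g in single},
                                      editing_sites=planted, n_fragments=800,
                                      read_len=60, fragment_len=150,
                                      error_rate=0.0, seed=13)
        res = pk.map_reads(reads, genome, 2)
        pile = pk.build_pileup(res.alignments, reads, genome)
        sites = pk.call_editing_sites(pile, genome, single, 5, 0.1)
        by_pos = {s.genomic_position: s for s in sites}
        for pos, _ in planted:
            site = by_pos[pos]
            n = sum(site.base_counts.values())
            lo, hi = stats.binom.interval(0.99, n, eff)
            assert lo <= site.base_counts[site.alt_base] <= hi

    def test_minus_strand_gene_reported_in_transcript_space(self):
        # genome G at the site; gene on minus strand => transcript base C;
        # RNA reads carrying T (genome space) are A on the transcript
        seq = "A" * 9 + "G" + "A" * 290
        genome = pk.Plastome(id="g", sequence=seq, circular=False)
        gene = pk.GeneModel(name="m", type="CDS", strand="-",
                            exons=[pk.Interval(1, 300)])
        pile = _pileup_with_column(genome, 10, {"G": (0, 4), "T": (0, 6)})
        (site,) = pk.call_editing_sites(pile, genome, [gene], 5, 0.1)
        assert site.genomic_position == 10
        assert (site.ref_base, site.alt_base) == ("C", "A")
        assert site.conversion == "C-to-A"


class TestCodonImpact:
    def _gene_with_cds(self, cds_dna, strand="+", offset=10):
        seq = "A" * offset + (cds_dna if strand == "+" else pk.revcomp(cds_dna)) \
            + "A" * 10
        genome = pk.Plastome(id="g", sequence=seq, circular=False)
        gene = pk.GeneModel(name="t", type="CDS", strand=strand,
                            exons=[pk.Interval(offset + 1, offset + len(cds_dna))])
        return genome, gene

    def test_stop_to_trp(self):
        # last codon TGA; A->G at the third position gives TGG (Trp)
        genome, gene = self._gene_with_cds("ATG" + "GCT" * 158 + "TGA")
        site = pk.EditingSite(gene="t", position_in_gene=480,
                              genomic_position=490, ref_base="A", alt_base="G",
                              base_counts={"A": 4, "G": 9}, efficiency=64.3,
                              conversion="A-to-G")
        site = pk.annotate_codon_change(site, gene, genome)
        assert site.codon_change == ("UGA", "UGG")
        assert site.aa_change == ("stop", "Trp")
        assert site.synonymous is False

    def test_tyr_to_stop(self):
        # codon 196 TAT; U->A at the third position gives TAA (stop)
        genome, gene = self._gene_with_cds("ATG" + "GCT" * 194 + "TAT")
        site = pk.EditingSite(gene="t", position_in_gene=588,
                              genomic_position=598, ref_base="U", alt_base="A",
                              base_counts={"A": 55, "U": 28}, efficiency=66.3,
                              conversion="U-to-A")
        site = pk.annotate_codon_change(site, gene, genome)
        assert site.codon_change == ("UAU", "UAA")
        assert site.aa_change == ("Tyr", "stop")

    def test_synonymous_third_position(self):
        genome, gene = self._gene_with_cds("ATG" + "TTC")
        site = pk.EditingSite(gene="t", position_in_gene=6, genomic_position=16,
                              ref_base="C", alt_base="U",
                              base_counts={"C": 2, "U": 10}, efficiency=83.3,
                              conversion="C-to-U")
        site = pk.annotate_codon_change(site, gene, genome)
        assert site.codon_change == ("UUC", "UUU")
        assert site.aa_change == ("Phe", "Phe")
        assert site.synonymous is True

    def test_non_cds_raises(self):
        genome, gene = self._gene_with_cds("ATGTAA")
        gene.type = "tRNA"
        site = pk.EditingSite(gene="t", position_in_gene=1, genomic_position=11,
                              ref_base="A", alt_base="G", base_counts={"A": 1},
                              efficiency=0.0, conversion="A-to-G")
        with pytest.raises(PositionNotInCDS):
            pk.annotate_codon_change(site, gene, genome)


class TestSpectrumAndConfirmation:
    def test_published_spectrum_has_17_c_to_u(self):
        sites = [
            pk.EditingSite(gene=row[0], position_in_gene=row[2],
                           genomic_position=i + 1, ref_base=row[5][0],
                           alt_base=row[5][-1], base_counts=row[6],
                           efficiency=0.0,
                           conversion=f"{row[5][0]}-to-{row[5][-1]}")
            for i, row in enumerate(pub.EDITING_TABLE)
        ]
        spectrum = pk.summarize_conversion_spectrum(sites)
        assert spectrum["C-to-U"] == 17
        assert sum(spectrum.values()) == 30

    def test_empty_input(self):
        assert pk.summarize_conversion_spectrum([]) == {}

    def test_confirm_predictions_set_algebra(self):
        out = pk.confirm_predictions([100, 200], [200, 300])
        assert out == {"confirmed": {200}, "predicted_only": {100},
                       "called_only": {300}}

    def test_identical_lists_all_confirmed(self):
        out = pk.confirm_predictions([1, 2, 3], [1, 2, 3])
        assert out["confirmed"] == {1, 2, 3}
        assert not out["predicted_only"] and not out["called_only"]

    def test_random_lists_match_brute_force(self):
        rng = np.random.default_rng(17)
        a = set(map(int, rng.integers(0, 50, size=20)))
        b = set(map(int, rng.integers(0, 50, size=20)))
        out = pk.confirm_predictions(sorted(a), sorted(b))
        assert out["confirmed"] == a & b
        assert out["predicted_only"] == a - b
        assert out["called_only"] == b - a
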