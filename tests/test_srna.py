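"""Small-RNA footprint calling, core sequences, context classes, orthologs."""

import numpy as np
import pytest

import plastidkit as pk
from plastidkit.exceptions import EmptyLocus
from plastidkit.srna import StrandCoverage, alignment_identity

from conftest import random_seq


def _aln(read_id, start, strand="+"):
    return pk.Alignment(read_id=read_id, start=start, strand=strand, mismatches=0)


class TestCoverage:
    def test_single_short_read(self):
        reads = [pk.Read(id="r", bases="A" * 21)]
        short, long_ = pk.size_stratified_coverage([_aln("r", 100)], reads, 500)
        assert short.plus[99:120].tolist() == [1] * 21
        assert short.total.sum() == 21
        assert long_.total.sum() == 0

    def test_empty_read_set(self):
        short, long_ = pk.size_stratified_coverage([], [], 100)
        assert short.total.sum() == 0 and long_.total.sum() == 0

    def test_matches_independent_overlap_count(self, quad_genome):
        genome, _ = quad_genome
        gene = pk.GeneModel(name="bg", type="CDS", strand="+",
                            exons=[pk.Interval(101, 700)])
        reads, _ = pk.simulate_srna(genome, [(pk.Interval(2000, 2020), 40)],
                                    background_genes=[gene], seed=5)
        res = pk.map_reads(reads, genome, 0)
        lookup = {r.id: r for r in reads}
        short, long_ = pk.size_stratified_coverage(res.alignments, reads, len(genome))
        # independent per-position overlap count
        exp_short = np.zeros(len(genome))
        exp_long = np.zeros(len(genome))
        for a in res.alignments:
            L = len(lookup[a.read_id])
            vec = exp_short if 20 <= L <= 24 else exp_long if L >= 31 else None
            if vec is not None:
                vec[a.start - 1: a.start - 1 + L] += 1
        assert (short.total == exp_short).all()
        assert (long_.total == exp_long).all()


class TestLocusCalling:
    def _cov(self, n, spans, depth, strand="+"):
        cov = StrandCoverage(np.zeros(n, dtype=int), np.zeros(n, dtype=int))
        vec = cov.plus if strand == "+" else cov.minus
        for a, b in spans:
            vec[a - 1: b] += depth
        return cov

    def test_long_read_only_coverage_gives_no_loci(self):
        n = 500
        short = self._cov(n, [], 0)
        long_ = self._cov(n, [(1, 500)], 1000)
        assert pk.call_srna_loci(short, long_, 20, 5, 10) == []

    def test_merge_rule(self):
        n = 500
        # two stacks separated by a 5 bp gap merge at merge_gap=10
        short = self._cov(n, [(100, 120), (126, 146)], 50)
        long_ = self._cov(n, [], 0)
        loci = pk.call_srna_loci(short, long_, 20, 5, 10)
        assert [(x.start, x.end) for x in loci] == [(100, 146)]
        loci = pk.call_srna_loci(short, long_, 20, 5, 3)
        assert [(x.start, x.end) for x in loci] == [(100, 120), (126, 146)]

    def test_enrichment_threshold_applies(self):
        n = 500
        short = self._cov(n, [(100, 120)], 30)
        long_ = self._cov(n, [(100, 120)], 30)  # ratio 30/31 < 5
        assert pk.call_srna_loci(short, long_, 20, 5, 10) == []

    def test_per_strand_calling(self):
        n = 500
        short = StrandCoverage(np.zeros(n, dtype=int), np.zeros(n, dtype=int))
        short.plus[99:120] = 25
        short.minus[299:320] = 25
        long_ = self._cov(n, [], 0)
        loci = pk.call_srna_loci(short, long_, 20, 5, 10)
        assert [(x.start, x.strand) for x in loci] == [(100, "+"), (300, "-")]

    def test_invariant_under_alignment_order(self, quad_genome):
        genome, _ = quad_genome
        reads, _ = pk.simulate_srna(genome, [(pk.Interval(900, 920), 60)], seed=6)
        res = pk.map_reads(reads, genome, 0)
        short, long_ = pk.size_stratified_coverage(res.alignments, reads, len(genome))
        fwd = pk.call_srna_loci(short, long_, 20, 5, 10,
                                alignments=res.alignments, reads=reads)
        rev_alns = list(reversed(res.alignments))
        short2, long2 = pk.size_stratified_coverage(rev_alns, reads, len(genome))
        rev = pk.call_srna_loci(short2, long2, 20, 5, 10,
                                alignments=rev_alns, reads=reads)
        assert [(x.start, x.end, x.core_sequence) for x in fwd] == \
            [(x.start, x.end, x.core_sequence) for x in rev]

    def test_planted_footprints_recovered_with_perfect_precision_recall(
        self, annotated_genome
    ):
        genome, _, genes, _ = annotated_genome
        footprints = [(pk.Interval(700, 720), 120), (pk.Interval(3100, 3121), 150),
                      (pk.Interval(5200, 5220), 100)]
        background = [g for g in genes if len(g.exons) == 1 and g.ir_copy_of is None][:3]
        reads, truth = pk.simulate_srna(genome, footprints,
                                        background_genes=background, seed=7)
        res = pk.map_reads(reads, genome, 0)
        short, long_ = pk.size_stratified_coverage(res.alignments, reads, len(genome))
        loci = pk.call_srna_loci(short, long_, 20, 5, 10,
                                 alignments=res.alignments, reads=reads)
        planted = [(f.start, f.end) for f in truth.footprints]
        called = [(x.start, x.end) for x in loci]
        assert len(called) == len(planted)  # precision = recall = 1
        for (ps, pe), (cs, ce) in zip(planted, called):
            assert abs(cs - ps) <= 2 and abs(ce - pe) <= 2  # end jitter only


class TestCoreSequence:
    def test_most_abundant_wins(self):
        reads = [pk.Read(id=f"x{i}", bases="ACGTACGTACGTACGTACGTA") for i in range(40)]
        reads += [pk.Read(id=f"y{i}", bases="TTTTACGTACGTACGTACGTT") for i in range(10)]
        alns = [_aln(r.id, 100) for r in reads]
        locus = pk.SRNALocus(start=100, end=120, strand="+")
        seq, count, strand = pk.core_sequence(locus, alns, reads)
        assert (seq, count, strand) == ("ACGTACGTACGTACGTACGTA", 40, "+")

    def test_tie_breaks_lexicographically(self):
        reads = [pk.Read(id=f"x{i}", bases="TTGTACGTACGTACGTACGTA") for i in range(5)]
        reads += [pk.Read(id=f"y{i}", bases="AAGTACGTACGTACGTACGTT") for i in range(5)]
        alns = [_aln(r.id, 100) for r in reads]
        locus = pk.SRNALocus(start=100, end=120, strand="+")
        seq, count, _ = pk.core_sequence(locus, alns, reads)
        assert seq.startswith("AA") and count == 5

    def test_empty_locus_raises(self):
        with pytest.raises(EmptyLocus):
            pk.core_sequence(pk.SRNALocus(start=10, end=30, strand="+"), [], [])

    def test_planted_core_recovered(self, quad_genome):
        genome, _ = quad_genome
        iv = pk.Interval(1500, 1520)
        reads, truth = pk.simulate_srna(genome, [(iv, 80)], seed=8)
        res = pk.map_reads(reads, genome, 0)
        locus = pk.SRNALocus(start=iv.start, end=iv.end, strand="+")
        seq, count, strand = pk.core_sequence(locus, res.alignments, reads)
        assert seq == truth.footprints[0].core_sequence
        assert strand == "+"


class TestLocation:
    def _genes(self):
        return [
            pk.GeneModel(name="plus", type="CDS", strand="+",
                         exons=[pk.Interval(1000, 1299), pk.Interval(1400, 1699)]),
            pk.GeneModel(name="minus", type="CDS", strand="-",
                         exons=[pk.Interval(3000, 3299)]),
        ]

    @pytest.mark.parametrize(
        "start,end,strand,expected",
        [
            (1100, 1120, "+", "CDS"),
            (1320, 1340, "+", "intron"),
            (930, 950, "+", "intergenic_5prime"),     # 60 bp upstream of start
            (1750, 1770, "+", "intergenic_3prime"),   # 61 bp past the stop
            (3310, 3330, "-", "intergenic_5prime"),   # upstream of minus-strand start
            (2000, 2020, "+", "intergenic_other"),
        ],
    )
    def test_classes(self, start, end, strand, expected):
        locus = pk.SRNALocus(start=start, end=end, strand=strand)
        assert pk.classify_locus_location(locus, self._genes()) == expected

    def test_matches_interval_oracle(self):
        from intervaltree import IntervalTree

        genes = self._genes()
        exons = IntervalTree()
        introns = IntervalTree()
        for g in genes:
            for e in g.exons:
                exons.addi(e.start, e.end + 1)
            for a, b in zip(g.exons, g.exons[1:]):
                introns.addi(a.end + 1, b.start)
        rng = np.random.default_rng(30)
        for _ in range(150):
            start = int(rng.integers(1, 4000))
            locus = pk.SRNALocus(start=start, end=start + 20, strand="+")
            got = pk.classify_locus_location(locus, genes)
            mid = locus.midpoint
            if exons.overlaps(mid):
                assert got == "CDS"
            elif introns.overlaps(mid):
                assert got == "intron"
            else:
                assert got.startswith("intergenic")


class TestOrthologs:
    def test_identical_sequences(self):
        assert alignment_identity("ACGTACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGTA") == 1.0

    def test_two_substitutions_in_21mer_pass_at_090(self):
        a = "ACGTACGTACGTACGTACGTA"
        b = "ACGTACTTACGTACGAACGTA"
        ident = alignment_identity(a, b)
        assert ident == pytest.approx(19 / 21)
        matches = pk.ortholog_match({"q": a}, {"r": b}, min_identity=0.90)
        assert matches == [("q", "r", pytest.approx(19 / 21))]

    def test_random_sequences_do_not_match(self):
        queries = {f"q{i}": random_seq(40 + i, 21) for i in range(5)}
        refs = {f"r{i}": random_seq(60 + i, 21) for i in range(5)}
        assert pk.ortholog_match(queries, refs, min_identity=0.90) == []
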