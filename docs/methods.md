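# Methods

This note records the models, defaults and numerical choices behind
plastidkit, and what the synthetic-data generator does and does not emulate.

## Coordinates and alphabets

All internal coordinates and every TSV report are 1-based inclusive, the
convention of printed plastome tables; conversion to 0-based happens only at
the GFF3/SAM/BED boundary (BED exports are 0-based half-open per that
standard). Genome sequences are DNA over {A,C,G,T,N}; editing reports use
the RNA alphabet (U) in transcript orientation. All CDS translation uses
NCBI table 11 (bacterial/plant plastid).

## Quadripartite structure

The partition is induced by the longest pair of disjoint, exactly
reverse-complementary maximal segments of length ≥ `min_ir_length`
(default 1,000 bp; real plastid IRs are 20–25 kb, so the default is
permissive while excluding dispersed repeats). The search is seed-and-extend
over the linear sequence with a left-maximality guard, so each maximal pair
is extended exactly once; an IR copy spanning the circular origin is not
detected (assembled plastomes are conventionally rotated so the origin lies
in the LSC). Two distinct candidate pairs tying at the maximum length raise
an error rather than guessing. Labels follow the standard map convention:
the longer single-copy region is the LSC and the IR that follows it in
circular order is IRb. N bases never match, and GC content excludes N from
the denominator.

## Gene models

A gene is a stranded list of exons in transcript order with type CDS, tRNA
or rRNA. Trans-spliced genes (the *rps12* pattern: an independent 5′ exon
joined in trans to a downstream part) are one model whose first inter-exon
junction is the trans junction; that junction is never reported as an
intron, and per-exon strands may differ. IR duplicates carry an
`ir_copy_of` link and count once in unique-gene totals and codon usage,
matching how published plastome tables count "unique genes". CDS lengths
not divisible by 3 warn and truncate; codons containing N are skipped with
a warning.

## Repeat survey

Maximal repeats are enumerated in forward, palindromic and
reverse-not-complemented orientations by the same seed-and-extend scheme
(complement-only repeats are not searched). The significance filter is the
expected count of chance pairs of the observed length in an i.i.d.
uniform-base sequence of the same size, E(l, n) = (n−l+1)(n−l)/2 · 4^(−l)
per orientation, with defaults min length 20 bp and E < 10⁻³. This plays
the role of the e-value used by classical repeat-survey tools; no claim is
made to reproduce any particular tool's statistic, and published repeat
counts that depend on such internals are out of scope. The two IR copies
themselves form one giant palindromic hit; it is suppressed by default
(flag to include) because a repeat survey counts dispersed repeats, not the
IR duplication. Location classes (CDS/intron/intergenic) are decided by
majority overlap of the first copy, ties favouring CDS then intron. A
quadratic brute-force enumerator is kept in the test suite as the
independent oracle; the two agree exactly on every sequence up to 3 kb used
in tests.

## Read mapping

The mapper is an exhaustive ungapped Hamming-distance scan of both strands
(vectorized over all placements), with circular wrap when the genome is
circular, N counting as a mismatch, and all equally-best placements
reported (`multi_hits` records their number; the deterministic primary
placement is the lowest coordinate, plus strand first). Defaults: ≤2
mismatches for mRNA reads, 0 for small-RNA reads. Gapped or spliced
alignment is deliberately absent: every downstream analysis here uses
substitution-level evidence only. Two consequences are documented rather
than patched: reads spanning a splice junction go unmapped (intron-bearing
genes are undercounted at the junction), and fragments of a trans-spliced
transcript can span two distant loci, so their genomic midpoints are
uninformative. Recovery tests therefore use intron-free genes; on real
data, junction-adjacent evidence should be interpreted accordingly.

## Expression

A fragment (mate pair collapsed; the first mate anchors, paired with the
closest placement of its mate) is assigned to a gene when its span midpoint
lies in an exon — midpoint rather than any-overlap assignment avoids double
counting at gene boundaries. Gene length for FPKM is exonic length only;
the library size is every fragment aligned anywhere on the plastome. Under
the default `all` multi-mapping policy a fragment equally-best in both IR
copies counts once in each copy, mirroring expression tables that list both
IR paralogs with near-equal values; `primary` restricts to the
lowest-coordinate placement, which keeps total assigned counts bounded by
the library size.

## RNA editing

A site is emitted where total non-N coverage ≥ `min_coverage` (default 5)
and the most frequent non-reference base reaches `min_alt_fraction`
(default 0.1) of all observed bases. The defaults are permissive because
genuine plastid sites can be supported by as few as two reads at ~16 %
conversion; both are flags. Editing efficiency is 100 × alt / (all observed
bases) to one decimal — the denominator is the full column, not ref+alt
only, which is what reproduces published per-site percentages when a third
base is present. The organellar reference is treated as haploid (no DNA
genotype heterogeneity); a DNA pileup can optionally confirm the reference
base. Sites inside a minus-strand gene are complemented into transcript
space before reporting, so conversion labels are strand-resolved. Codon
impact substitutes the alternate base at the site's codon offset and
translates both codons under table 11, labelling stops "stop". Sites
outside any exon are labelled with the nearest gene end within 300 bp
(5′/3′ UTR) or "intergenic". `confirm_predictions` intersects an external
candidate list (e.g. from a computational editing predictor) with called
sites by exact position; the prediction algorithm itself is out of scope.

## Small-RNA footprints

Per-base, per-strand coverage is accumulated separately for 20–24 nt reads
(the footprint size class) and >30 nt reads (fragments of abundant RNAs).
A locus is a maximal run, per strand, with short coverage ≥ `min_reads`
(default 20, the smallest support published for such loci) and
short/(long+1) ≥ `enrichment_ratio` (default 5; the +1 pseudo-count
tolerates zero background); runs closer than `merge_gap` (default 10 nt)
merge. The core sequence is the most abundant unique supporting read, ties
broken lexicographically; the locus strand is the majority read strand.
Context classes use the locus midpoint: CDS if in an exon, intron if in an
intron, otherwise intergenic sub-classed 5′-proximal within (−150, +50) bp
of a same-strand start codon and 3′-proximal within 100 bp of a stop codon.
Ortholog matching computes global (Needleman–Wunsch, unit-cost) alignment
identity = matches / alignment length via edlib, default threshold 0.90.

## Synthetic data

The generator is fully deterministic per seed (identical configuration +
seed ⇒ byte-identical FASTA/GFF3/FASTQ) and serializes its ground truth next
to the outputs; recovery tests read only that truth object.

* **Genome**: LSC + IR + SSC + revcomp(IR) with i.i.d. bases at target GC
  (default 0.38, the typical grass-plastome value). The last SSC base is
  patched when needed so the planted IR pair is maximal exactly at its
  boundaries; without this a ¼-chance flanking match would extend the
  detected IR by one base and break exact boundary recovery.
* **Genes**: non-overlapping CDS genes of length 300 bp (multiples of 3),
  optionally intron-bearing, IR duplicates at mirrored coordinates on
  opposite strands (their transcripts are identical by construction), and
  an optional two-part trans-spliced gene.
* **mRNA-seq**: fixed-length fragments (default 300 bp; a fixed length
  suffices for midpoint/FPKM semantics) drawn per gene ∝ rate × length and
  placed uniformly along the spliced transcript; each *molecule* covering a
  planted editing site carries the alternate base with probability equal to
  the site's efficiency (both mates consistently), then uniform
  substitution errors at 0.1 % per base. Qualities are constant; no indels,
  no quality-aware behaviour anywhere downstream to exercise.
* **Small RNA**: per footprint, `depth` reads share the core sequence with
  end jitter drawn from {−2..+2} weighted (0.10, 0.15, 0.50, 0.15, 0.10) —
  protected termini are sharply defined, so the exact core is always the
  modal read — clamped to 20–24 nt; background reads are 31–35 nt fragments
  tiled across designated genes.

What the generator does **not** emulate: realistic Illumina error/quality
profiles, indels, nuclear contamination, RNA degradation gradients, strand
biases, or SRA-scale volumes. Passing recovery tests therefore demonstrate
the correctness of the algorithms under their stated models, not robustness
to every artifact of real libraries. Test problem sizes (6–9 kb genomes,
hundreds to thousands of reads, ~50× coverage) were chosen as the smallest
scales at which each statistic is informative.

## Known limitations

* Real plastomes at 135 kb are handled by the structure, repeat and
  accounting stages in seconds; the exhaustive mapper is for desk-scale read
  sets (external aligners can substitute through the SAM interface).
* Published full-data catalogues that depend on SRA-scale read archives or
  on unpublished tool internals (total repeat counts, the complete sRNA
  locus catalogue, absolute FPKM values) are out of scope; the package
  reproduces the table *semantics* and the printed summary statistics.
* The editing caller assumes substitution-only editing (no U-insertion) and
  a haploid reference.
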