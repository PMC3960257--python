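"""Exception and warning types raised across the toolkit."""


class PlastidKitError(Exception):
    """Base class for all toolkit errors."""


class NoInvertedRepeat(PlastidKitError):
    """No disjoint reverse-complementary segment pair of the required length exists."""


class AmbiguousStructure(PlastidKitError):
    """Two non-nested candidate inverted-repeat pairs tie in length."""


class EmptyInterval(PlastidKitError):
    """An interval contains no informative (non-N) bases."""


class DanglingDuplicateLink(PlastidKitError):
    """A gene's ir_copy_of points at a name absent from the annotation."""


class PositionOutOfGene(PlastidKitError):
    """A transcript or genomic coordinate falls outside the gene's exons."""


class ZeroCoverage(PlastidKitError):
    """No reads observed at a site where a rate is requested."""


class PositionNotInCDS(PlastidKitError):
    """A site lies outside any protein-coding exon."""


class ZeroLengthGene(PlastidKitError):
    """FPKM requested for a gene with no exonic length."""


class EmptyLibrary(PlastidKitError):
    """FPKM requested against a library with zero mapped fragments."""


class EmptyLocus(PlastidKitError):
    """A small-RNA locus has no supporting reads."""


class MalformedRecord(PlastidKitError):
    """An input file record could not be parsed; carries an approximate line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (near line {line})"
        super().__init__(message)


class InsufficientSpace(PlastidKitError):
    """The genome is too short for the requested planted features."""


class ConfigError(PlastidKitError):
    """Invalid pipeline configuration."""


class LengthNotMultipleOfThree(UserWarning):
    """A CDS length is not divisible by 3; trailing bases are truncated."""


class AmbiguousBaseWarning(UserWarning):
    """A codon containing N was skipped."""
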