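"""Exception hierarchy for covplot.

Every error raised on purpose by the package derives from :class:`CovplotError`,
so callers (and the CLI) can distinguish user/data problems from bugs.
"""


class CovplotError(Exception):
    """Base class for all covplot errors."""


class InvalidRegionError(CovplotError, ValueError):
    """A genomic region violates its invariants (empty, negative, unnamed)."""


class RegionParseError(CovplotError, ValueError):
    """A region string could not be parsed as ``chrom:start-end``."""


class OutOfRangeError(CovplotError, ValueError):
    """A requested sub-region is not contained in the available region."""


class FormatError(CovplotError, ValueError):
    """An input file does not conform to its declared format."""


class SchemaError(CovplotError, ValueError):
    """A table or config is missing required columns/keys (named in message)."""


class ChromosomeNotFoundError(CovplotError, KeyError):
    """The requested chromosome is absent from a file's header or index."""


class IndexRequiredError(CovplotError, IOError):
    """An alignment file lacks the index needed for region-subset loading."""


class ReferenceUnavailableError(CovplotError, ValueError):
    """The FASTA reference does not cover the requested region."""


class ParameterError(CovplotError, ValueError):
    """An argument is outside its allowed domain (binsize < 1, bad gamma...)."""


class EmptyLibraryError(CovplotError, ValueError):
    """An alignment file contains zero usable mapped reads."""


class NotFoundError(CovplotError, KeyError):
    """A named entity (gene id, theme, chromosome band) does not exist."""


class SequenceError(CovplotError, ValueError):
    """A nucleotide or amino-acid sequence contains illegal characters."""


class CompositionError(CovplotError, ValueError):
    """An illegal layer composition (two coverage layers, mixed spaces)."""


class CoordinateSpaceError(CompositionError):
    """Genomic and protein layers were mixed in one figure."""
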