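"""Exception hierarchy.

All domain errors derive from :class:`PepfeatError`, itself a ``ValueError``,
so callers can catch everything with one except clause while the CLI maps
them to a non-zero exit code.
"""


class PepfeatError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidSymbolError(PepfeatError):
    """A character is not a canonical amino-acid letter (or known PTM tag)."""


class IllegalModificationError(PepfeatError):
    """A PTM tag was applied to a base residue it is not legal for."""


class EmptyInputError(PepfeatError):
    """An empty sequence or file where at least one residue is required."""


class LengthError(PepfeatError):
    """A length constraint was violated (padding too short, peptide too short)."""


class MalformedMatrixError(PepfeatError):
    """A one-hot matrix row does not contain exactly one 1."""


class InvalidLabelError(PepfeatError):
    """An integer label is outside the vocabulary index range."""


class CatalogError(PepfeatError):
    """An unknown descriptor or property name was requested."""


class RangeError(PepfeatError):
    """A numeric argument is outside its valid range (e.g. pH, probability)."""


class FileFormatError(PepfeatError):
    """A FASTA or CSV input file is malformed."""
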