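"""Exception hierarchy.

Every error raised by the library derives from :class:`RamzmlError`, so CLI
and batch callers can catch a single type. Parse-time errors carry the
1-based line number of the offending row when one is known.
"""


class RamzmlError(Exception):
    """Base class for all library errors."""


class ParseError(RamzmlError):
    """Malformed numeric field or row in a vendor text file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownDialect(RamzmlError):
    """Auto-detection could not identify the vendor text layout."""


class AxisMismatch(ParseError):
    """A pixel's Raman-shift axis differs from the first pixel's."""


class RaggedPixel(ParseError):
    """Pixels in a long-format file have differing channel counts."""


class DimensionMismatch(ParseError):
    """Wide-format spectrum count does not equal width x height."""


class IrregularGrid(RamzmlError):
    """Stage coordinates do not sit on a regular rectangular lattice."""


class EmptyMap(RamzmlError):
    """Map has no pixels or an empty spectral axis."""


class SparseMapUnsupported(RamzmlError):
    """Wide-format output requires a spectrum in every grid cell."""


class EmptyWindow(RamzmlError):
    """Requested Raman-shift window contains no spectral channel."""


class DomainError(RamzmlError):
    """Argument outside the mathematical domain (e.g. theoretical mass <= 0)."""


class MalformedXML(RamzmlError):
    """The imzML XML document could not be parsed or lacks required terms."""


class OffsetOutOfBounds(RamzmlError):
    """A declared binary region extends past the end of the .ibd file."""


class ChecksumMismatch(RamzmlError):
    """Stored SHA-1 does not match the .ibd file contents (strict mode)."""


class ChecksumWarning(UserWarning):
    """Non-strict notification that the .ibd checksum does not match."""


class IOFailure(RamzmlError):
    """File system error wrapped with path context."""
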