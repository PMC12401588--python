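"""Exception hierarchy.

The CLI maps these onto exit codes: usage/configuration errors exit 1,
parse/format/encoding errors exit 2, I/O errors exit 3.
"""


class ReadQCError(Exception):
    """Base class for all readqc errors."""


class ConfigurationError(ReadQCError):
    """Invalid parameter combination (e.g. overlapping include/exclude lists)."""


class FormatDetectionError(ReadQCError):
    """File content matches no supported read format."""


class ParseError(ReadQCError):
    """Malformed record inside an otherwise recognised file."""


class QualityEncodingError(ParseError):
    """Quality character outside the Sanger ASCII 33-126 range."""


class SnapshotError(ReadQCError):
    """Base class for snapshot (.rd) file problems."""


class NotASnapshotError(SnapshotError):
    """Magic bytes do not identify a snapshot file."""


class SnapshotVersionError(SnapshotError):
    """Snapshot format version not supported by this build."""


class CorruptSnapshotError(SnapshotError):
    """Payload truncated, size mismatch, or gzip failure."""
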