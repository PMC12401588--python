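"""Core record types shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Format(Enum):
    """Supported read-file container formats."""

    FASTA = "fasta"
    FASTQ = "fastq"
    SAM = "sam"
    BAM = "bam"
    CRAM = "cram"


@dataclass(frozen=True)
class FormatTag:
    """Result of content-based format detection.

    ``compressed`` refers to a plain gzip wrapper around FASTA/FASTQ text;
    BAM (BGZF) and CRAM are inherently compressed and carry ``compressed=False``
    here because no outer wrapper is involved.  ``empty`` flags a zero-byte
    file, reported as FASTA by convention.
    """

    kind: Format
    compressed: bool = False
    empty: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        suffix = ".gz" if self.compressed else ""
        return f"{self.kind.value}{suffix}"


@dataclass(slots=True)
class ReadRecord:
    """One sequencing read.

    ``name`` is the read identity: everything before the first whitespace of
    the original header.  ``comment`` keeps the remainder of the header so
    FASTA/FASTQ re-emission is faithful.  ``sequence`` is uppercased on
    ingest.  ``quality`` is the Sanger-encoded string (offset 33) or ``None``
    when the source format carries no quality (FASTA, or SAM/BAM/CRAM records
    with QUAL ``*``).
    """

    name: str
    sequence: str
    quality: Optional[str] = None
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.name!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# A read whose quality is entirely '!' (Q0) is treated as quality-absent by
# the statistics layer: Q0 placeholders are what FASTA up-conversion writes,
# and counting them would deflate quality aggregates.
PLACEHOLDER_QUALITY_CHAR = "!"


def has_informative_quality(record: ReadRecord) -> bool:
    """True when the record carries quality that should enter Q aggregates."""
    q = record.quality
    if q is None or len(q) == 0:
        return False
    return q.count(PLACEHOLDER_QUALITY_CHAR) != len(q)
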