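"""Content-based format detection, reading and writing of read files.

All five container formats (FASTA, FASTQ, SAM, BAM, CRAM, plus gzip
wrappers around the text formats) are exposed as one uniform stream of
:class:`~readqc.records.ReadRecord`.  Parsing and writing of the htslib
formats is delegated to pysam; FASTA/FASTQ text is emitted directly so
gzip members can be written deterministically (mtime zeroed).
"""

from __future__ import annotations

import gzip
import logging
import os
import zlib
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Union

import pysam

from .errors import FormatDetectionError, ParseError
from .records import Format, FormatTag, ReadRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

GZIP_MAGIC = b"\x1f\x8b"
CRAM_MAGIC = b"CRAM"
BAM_MAGIC = b"BAM\x01"

_SAM_HEADER_TAGS = {"HD", "SQ", "RG", "PG", "CO"}

# secondary (0x100) and supplementary (0x800): skip so each physical read
# is counted exactly once
_SKIP_FLAGS = 0x100 | 0x800

#: Q0 placeholder written when up-converting quality-less input to a
#: quality-bearing format.
PLACEHOLDER_QUALITY = "!"

_EXTENSION_MAP = {
    ".fasta": FormatTag(Format.FASTA),
    ".fa": FormatTag(Format.FASTA),
    ".fna": FormatTag(Format.FASTA),
    ".fastq": FormatTag(Format.FASTQ),
    ".fq": FormatTag(Format.FASTQ),
    ".sam": FormatTag(Format.SAM),
    ".bam": FormatTag(Format.BAM),
    ".cram": FormatTag(Format.CRAM),
}


def format_from_path(path: PathLike) -> FormatTag:
    """Infer an output FormatTag from a file extension (.gz aware)."""
    p = Path(path)
    suffixes = [s.lower() for s in p.suffixes[-2:]]
    compressed = bool(suffixes) and suffixes[-1] == ".gz"
    ext = suffixes[-2] if compressed and len(suffixes) == 2 else (
        suffixes[-1] if suffixes else ""
    )
    if compressed and ext not in (".fasta", ".fa", ".fna", ".fastq", ".fq"):
        raise FormatDetectionError(
            f"{path}: .gz wrapper is only supported for FASTA/FASTQ output"
        )
    tag = _EXTENSION_MAP.get(ext)
    if tag is None:
        raise FormatDetectionError(
            f"{path}: cannot infer output format from extension {ext!r}"
        )
    return FormatTag(tag.kind, compressed=compressed)


def _looks_like_sam(text: str) -> bool:
    for line in text.splitlines():
        if not line:
            continue
        if line.startswith("@"):
            if line[1:3] in _SAM_HEADER_TAGS and ("\t" in line or len(line) == 3):
                return True
            return False  # '@' but not a SAM header tag: FASTQ
        return line.count("\t") >= 10  # headerless alignment line
    return False


def _detect_text(head: str, path: PathLike) -> Format:
    stripped = head.lstrip("\n\r")
    if not stripped:
        raise FormatDetectionError(f"{path}: file contains only blank lines")
    first = stripped[0]
    if first == ">":
        return Format.FASTA
    if first == "@":
        return Format.SAM if _looks_like_sam(stripped) else Format.FASTQ
    if _looks_like_sam(stripped):
        return Format.SAM
    raise FormatDetectionError(f"{path}: unrecognised content (starts {first!r})")


def detect_format(path: PathLike) -> FormatTag:
    """Detect a file's format from its content, never from its name.

    gzip is recognised by magic bytes 1F 8B; BAM by the BGZF-wrapped
    ``BAM\\x01`` magic; CRAM by its ``CRAM`` magic; SAM/FASTA/FASTQ by
    inspecting the leading text.  An empty file is reported as FASTA with
    ``empty=True``.
    """
    with open(path, "rb") as fh:
        head = fh.read(4)
    if len(head) == 0:
        logger.warning("%s: empty file, treating as an empty FASTA stream", path)
        return FormatTag(Format.FASTA, empty=True)
    if head.startswith(CRAM_MAGIC):
        return FormatTag(Format.CRAM)
    if head.startswith(GZIP_MAGIC):
        # BGZF (hence BAM) is a gzip variant: decompress the head and look
        # for the inner magic, falling back to text sniffing.
        try:
            with gzip.open(path, "rb") as gz:
                inner = gz.read(8192)
        except (OSError, EOFError, zlib.error) as exc:
            raise ParseError(f"{path}: corrupt gzip stream ({exc})") from exc
        if inner.startswith(BAM_MAGIC):
            return FormatTag(Format.BAM)
        kind = _detect_text(inner.decode("latin-1"), path)
        if kind is Format.SAM:
            return FormatTag(Format.SAM)  # gzipped SAM: htslib reads it
        return FormatTag(kind, compressed=True)
    with open(path, "rt", encoding="latin-1") as fh:
        text = fh.read(8192)
    return FormatTag(_detect_text(text, path))


def _iter_fastx(path: PathLike) -> Iterator[ReadRecord]:
    try:
        with pysam.FastxFile(str(path)) as fx:
            for entry in fx:
                yield ReadRecord(
                    name=entry.name,
                    sequence=(entry.sequence or "").upper(),
                    quality=entry.quality,
                    comment=entry.comment,
                )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


@contextmanager
def _quiet_pysam():
    level = pysam.set_verbosity(0)
    try:
        yield
    finally:
        pysam.set_verbosity(level)


def _iter_alignments(path: PathLike, mode: str, threads: int) -> Iterator[ReadRecord]:
    with _quiet_pysam():
        af = pysam.AlignmentFile(
            str(path), mode, check_sq=False, threads=max(1, threads)
        )
    try:
        for rec in af.fetch(until_eof=True):
            if rec.flag & _SKIP_FLAGS:
                continue
            seq = rec.query_sequence
            if seq is None:
                logger.warning(
                    "%s: record %s has no sequence, skipped", path, rec.query_name
                )
                continue
            yield ReadRecord(
                name=rec.query_name,
                sequence=seq.upper(),
                quality=rec.qual,  # None when QUAL is '*'
            )
    except OSError as exc:
        raise ParseError(f"{path}: truncated or corrupt file ({exc})") from exc
    finally:
        af.close()


def read_file(path: PathLike, threads: int = 1) -> Iterator[ReadRecord]:
    """Stream one file as ReadRecords, whatever its format."""
    tag = detect_format(path)
    if tag.empty:
        return iter(())
    if tag.kind in (Format.FASTA, Format.FASTQ):
        return _iter_fastx(path)
    mode = {"sam": "r", "bam": "rb", "cram": "rc"}[tag.kind.value]
    return _iter_alignments(path, mode, threads)


def open_reads(paths: Sequence[PathLike], threads: int = 1) -> Iterator[ReadRecord]:
    """Stream several files (formats may differ) as one concatenated stream,
    files in argument order, records in file order."""
    for path in paths:
        yield from read_file(path, threads=threads)


# ---------------------------------------------------------------------------
# writing


def _write_fastx(
    records: Iterable[ReadRecord], path: PathLike, tag: FormatTag
) -> int:
    fasta = tag.kind is Format.FASTA
    if tag.compressed:
        # mtime=0 so identical content gives identical bytes
        raw = open(path, "wb")
        fh = gzip.GzipFile(
            filename="", fileobj=raw, mode="wb", mtime=0, compresslevel=6
        )
    else:
        raw = None
        fh = open(path, "wb")
    n = 0
    warned_drop = False
    try:
        for rec in records:
            header = rec.name if rec.comment is None else f"{rec.name} {rec.comment}"
            if fasta:
                if rec.quality is not None and not warned_drop:
                    logger.warning(
                        "writing FASTA drops quality strings (lossy conversion)"
                    )
                    warned_drop = True
                fh.write(f">{header}\n{rec.sequence}\n".encode("latin-1"))
            else:
                qual = rec.quality
                if qual is None:
                    qual = PLACEHOLDER_QUALITY * len(rec.sequence)
                fh.write(
                    f"@{header}\n{rec.sequence}\n+\n{qual}\n".encode("latin-1")
                )
            n += 1
    finally:
        fh.close()
        if raw is not None:
            raw.close()
    return n


_UNALIGNED_HEADER = {"HD": {"VN": "1.6", "SO": "unknown"}}


def _write_alignments(
    records: Iterable[ReadRecord], path: PathLike, tag: FormatTag, threads: int
) -> int:
    mode = {"sam": "w", "bam": "wb", "cram": "wc"}[tag.kind.value]
    kwargs = {"threads": max(1, threads)}
    if tag.kind is Format.CRAM:
        # unaligned reads, no reference available: store sequences verbatim
        kwargs["format_options"] = [b"no_ref=1"]
    warned_placeholder = False
    n = 0
    with _quiet_pysam():
        af = pysam.AlignmentFile(str(path), mode, header=_UNALIGNED_HEADER, **kwargs)
    try:
        for rec in records:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = rec.name
            seg.query_sequence = rec.sequence
            seg.flag = 4  # unmapped
            seg.reference_id = -1
            seg.reference_start = -1
            seg.mapping_quality = 0
            qual = rec.quality
            if qual is None and len(rec.sequence):
                qual = PLACEHOLDER_QUALITY * len(rec.sequence)
                if not warned_placeholder:
                    logger.warning(
                        "quality-less reads written with Q0 placeholder quality"
                    )
                    warned_placeholder = True
            if qual is not None:
                seg.query_qualities = pysam.qualitystring_to_array(qual)
            af.write(seg)
            n += 1
    finally:
        af.close()
    return n


def write_reads(
    records: Iterable[ReadRecord],
    path: PathLike,
    fmt: Union[FormatTag, str, None] = None,
    threads: int = 1,
) -> int:
    """Write a record stream to ``path`` in the requested format.

    ``fmt`` may be a FormatTag, an extension-like string ("fastq.gz",
    "bam", ...), or None to infer from the path.  Returns the number of
    records written.  FASTA output drops quality (warned once); writing
    quality-less reads into a quality-bearing format uses a constant Q0
    placeholder that the statistics layer recognises and excludes.
    """
    if fmt is None:
        tag = format_from_path(path)
    elif isinstance(fmt, FormatTag):
        tag = fmt
    else:
        tag = format_from_path(f"x.{str(fmt).lstrip('.')}")
    if tag.kind in (Format.FASTA, Format.FASTQ):
        return _write_fastx(records, path, tag)
    return _write_alignments(records, path, tag, threads)


def file_size(path: PathLike) -> int:
    return os.path.getsize(path)
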