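"""The .rd snapshot: a tiny, mergeable binary digest of a read dataset.

A snapshot stores everything the statistics and report layers need —
sorted per-read lengths, quantized per-read mean qualities, dataset base
composition, and the provenance (path, size, md5, read count) of every
input file — but not the reads themselves: sequences are irrecoverable
by construction.

Byte layout (this package's own, documented here; little-endian
throughout):

    magic    4 bytes  b"RDQC"
    version  uint16   currently 1
    flags    uint8    bit 0: median-quality array present
    n_src    uint32
    per source:
        path_len uint16, path utf-8 bytes,
        byte_size uint64, md5 16 bytes, read_count uint64
    payload_size uint64   (uncompressed payload bytes)
    payload  gzip-compressed (level 6, mtime 0 -> byte-deterministic):
        base_totals 6 x uint64 (A C G T N other)
        n_reads     uint64
        width       uint8, smallest of {1, 2, 8} bytes holding max length
        lengths     n_reads x width, sorted descending
        mean_q      n_reads x uint8, Q rounded half-up to 0..93, 255 = absent
        [median_q   n_reads x uint8, same encoding, when flagged]
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import os
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    CorruptSnapshotError,
    NotASnapshotError,
    SnapshotVersionError,
)
from .metrics import MAX_QUALITY, DatasetStats

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MAGIC = b"RDQC"
VERSION = 1
ABSENT_Q = 255
_FLAG_MEDIAN = 0x01

_WIDTH_DTYPES = {1: "<u1", 2: "<u2", 8: "<u8"}


def md5_file(path: PathLike, chunk: int = 1 << 20) -> bytes:
    """MD5 digest (16 bytes) of a file's on-disk bytes, exactly as stored."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        while block := fh.read(chunk):
            h.update(block)
    return h.digest()


@dataclass(frozen=True)
class SourceInfo:
    """Provenance of one input file."""

    path: str
    byte_size: int
    md5: bytes  # 16 raw bytes
    read_count: int

    @classmethod
    def from_file(cls, path: PathLike, read_count: int) -> "SourceInfo":
        return cls(
            path=str(path),
            byte_size=os.path.getsize(path),
            md5=md5_file(path),
            read_count=read_count,
        )

    @property
    def md5_hex(self) -> str:
        return self.md5.hex()


@dataclass
class SnapshotHeader:
    version: int = VERSION
    sources: List[SourceInfo] = field(default_factory=list)
    payload_size: int = 0
    has_median: bool = False


def choose_width(max_length: int) -> int:
    """Smallest of {1, 2, 8} bytes representing every stored length."""
    if max_length < 1 << 8:
        return 1
    if max_length < 1 << 16:
        return 2
    return 8


def quantize_q(mean_qs: np.ndarray) -> np.ndarray:
    """Per-read mean Q -> uint8: rounded half-up, clipped to 0..93; NaN -> 255."""
    out = np.full(mean_qs.shape, ABSENT_Q, dtype=np.uint8)
    present = ~np.isnan(mean_qs)
    out[present] = np.clip(
        np.floor(mean_qs[present] + 0.5), 0, MAX_QUALITY
    ).astype(np.uint8)
    return out


def quantized(stats: DatasetStats) -> DatasetStats:
    """The stats as a snapshot round trip reproduces them: lengths and base
    totals exact, per-read Q quantized to integers."""
    q = quantize_q(stats.mean_qs)
    mean_qs = np.where(q == ABSENT_Q, np.nan, q.astype(np.float64))
    med = None
    if stats.median_qs is not None:
        mq = quantize_q(stats.median_qs)
        med = np.where(mq == ABSENT_Q, np.nan, mq.astype(np.float64))
    return DatasetStats(
        lengths=stats.lengths.copy(),
        mean_qs=mean_qs,
        base_totals=stats.base_totals.copy(),
        median_qs=med,
    )


def _encode_payload(stats: DatasetStats) -> bytes:
    n = stats.n_reads
    width = choose_width(stats.length_max or 0)
    parts = [
        np.asarray(stats.base_totals, dtype="<u8").tobytes(),
        struct.pack("<QB", n, width),
        stats.lengths.astype(_WIDTH_DTYPES[width]).tobytes(),
        quantize_q(stats.mean_qs).tobytes(),
    ]
    if stats.median_qs is not None:
        parts.append(quantize_q(stats.median_qs).tobytes())
    return b"".join(parts)


def _decode_payload(data: bytes, has_median: bool) -> DatasetStats:
    try:
        base_totals = np.frombuffer(data[:48], dtype="<u8").astype(np.int64)
        n, width = struct.unpack_from("<QB", data, 48)
        if width not in _WIDTH_DTYPES:
            raise CorruptSnapshotError(f"invalid length width {width}")
        off = 57
        lengths = np.frombuffer(
            data[off : off + n * width], dtype=_WIDTH_DTYPES[width]
        ).astype(np.int64)
        off += n * width
        qbytes = np.frombuffer(data[off : off + n], dtype=np.uint8)
        off += n
        if lengths.size != n or qbytes.size != n:
            raise CorruptSnapshotError("payload shorter than declared arrays")
        mean_qs = np.where(qbytes == ABSENT_Q, np.nan, qbytes.astype(np.float64))
        median_qs = None
        if has_median:
            mbytes = np.frombuffer(data[off : off + n], dtype=np.uint8)
            if mbytes.size != n:
                raise CorruptSnapshotError("median array truncated")
            median_qs = np.where(
                mbytes == ABSENT_Q, np.nan, mbytes.astype(np.float64)
            )
    except struct.error as exc:
        raise CorruptSnapshotError(f"payload truncated ({exc})") from exc
    return DatasetStats(
        lengths=lengths,
        mean_qs=mean_qs,
        base_totals=base_totals,
        median_qs=median_qs,
    )


def snapshot_write(
    stats: DatasetStats,
    sources: Sequence[SourceInfo],
    path: PathLike,
) -> int:
    """Serialize stats + provenance to ``path``; returns bytes written.

    Output is byte-deterministic for identical inputs (fixed gzip level,
    zeroed gzip mtime).
    """
    payload = _encode_payload(stats)
    compressed = gzip.compress(payload, compresslevel=6, mtime=0)
    flags = _FLAG_MEDIAN if stats.median_qs is not None else 0
    head = [MAGIC, struct.pack("<HBI", VERSION, flags, len(sources))]
    for src in sources:
        p = src.path.encode("utf-8")
        if len(src.md5) != 16:
            raise ValueError("md5 digest must be 16 raw bytes")
        head.append(struct.pack("<H", len(p)))
        head.append(p)
        head.append(struct.pack("<Q", src.byte_size))
        head.append(src.md5)
        head.append(struct.pack("<Q", src.read_count))
    head.append(struct.pack("<Q", len(payload)))
    blob = b"".join(head) + compressed
    with open(path, "wb") as fh:
        fh.write(blob)
    return len(blob)


def snapshot_read(path: PathLike) -> Tuple[DatasetStats, SnapshotHeader]:
    """Read a snapshot back; verifies magic, version and payload size."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[:4] != MAGIC:
        raise NotASnapshotError(f"{path}: not a snapshot file (bad magic)")
    try:
        version, flags, n_src = struct.unpack_from("<HBI", blob, 4)
        if version != VERSION:
            raise SnapshotVersionError(
                f"{path}: snapshot version {version} not supported (expected {VERSION})"
            )
        off = 11
        sources = []
        for _ in range(n_src):
            (plen,) = struct.unpack_from("<H", blob, off)
            off += 2
            p = blob[off : off + plen].decode("utf-8")
            off += plen
            (byte_size,) = struct.unpack_from("<Q", blob, off)
            off += 8
            md5 = blob[off : off + 16]
            off += 16
            (read_count,) = struct.unpack_from("<Q", blob, off)
            off += 8
            sources.append(SourceInfo(p, byte_size, md5, read_count))
        (payload_size,) = struct.unpack_from("<Q", blob, off)
        off += 8
    except struct.error as exc:
        raise CorruptSnapshotError(f"{path}: header truncated") from exc
    try:
        payload = gzip.decompress(blob[off:])
    except (OSError, EOFError, zlib.error) as exc:
        raise CorruptSnapshotError(f"{path}: payload gzip failure ({exc})") from exc
    if len(payload) != payload_size:
        raise CorruptSnapshotError(
            f"{path}: payload size mismatch "
            f"(header says {payload_size}, got {len(payload)})"
        )
    has_median = bool(flags & _FLAG_MEDIAN)
    stats = _decode_payload(payload, has_median)
    header = SnapshotHeader(
        version=version,
        sources=sources,
        payload_size=payload_size,
        has_median=has_median,
    )
    return stats, header


def merge_stats(parts: Sequence[DatasetStats]) -> DatasetStats:
    """Combine statistics as if computed on the concatenated read streams."""
    lengths = np.concatenate([p.lengths for p in parts]) if parts else np.empty(0, np.int64)
    qs = np.concatenate([p.mean_qs for p in parts]) if parts else np.empty(0, np.float64)
    base_totals = np.zeros(6, dtype=np.int64)
    for p in parts:
        base_totals += np.asarray(p.base_totals, dtype=np.int64)
    med = None
    if parts and all(p.median_qs is not None for p in parts):
        med = np.concatenate([p.median_qs for p in parts])
    order = np.argsort(-lengths, kind="stable")
    return DatasetStats(
        lengths=lengths[order],
        mean_qs=qs[order],
        base_totals=base_totals,
        median_qs=None if med is None else med[order],
    )


def snapshot_merge(paths: Sequence[PathLike], out: PathLike) -> int:
    """Merge snapshots into one equal to a snapshot of the concatenated
    inputs.  Duplicate source md5s across inputs are flagged (possible
    double counting) but the merge proceeds."""
    parts, sources = [], []
    seen_md5 = set()
    for p in paths:
        stats, header = snapshot_read(p)
        parts.append(stats)
        for src in header.sources:
            if src.md5 in seen_md5:
                logger.warning(
                    "duplicate source md5 %s (%s): statistics may double-count",
                    src.md5_hex,
                    src.path,
                )
            seen_md5.add(src.md5)
            sources.append(src)
    merged = merge_stats(parts)
    return snapshot_write(merged, sources, out)
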