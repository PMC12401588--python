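"""Homopolymer compression: collapse runs of identical bases to at most k.

A lossy preprocessing step common in long-read workflows, where platform
errors concentrate in homopolymer length calls.  The collapse is one
linear pass with constant auxiliary state (vectorised run detection, no
per-run buffers); quality, when present, keeps the first k characters of
each run so the length invariant holds.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

import numpy as np

from .errors import ConfigurationError
from .records import ReadRecord


def _keep_mask(seq_bytes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask keeping at most the first k positions of each maximal run."""
    n = seq_bytes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    if k == 1:
        mask = np.empty(n, dtype=bool)
        mask[0] = True
        np.not_equal(seq_bytes[1:], seq_bytes[:-1], out=mask[1:])
        return mask
    starts = np.empty(n, dtype=bool)
    starts[0] = True
    np.not_equal(seq_bytes[1:], seq_bytes[:-1], out=starts[1:])
    start_idx = np.flatnonzero(starts)
    # offset within current run = position - position of the run's start
    offsets = np.arange(n) - np.repeat(start_idx, np.diff(np.append(start_idx, n)))
    return offsets < k


def homopolymer_compress(record: ReadRecord, k: int = 1) -> ReadRecord:
    """Collapse every maximal run longer than k to exactly k bases.

    Runs of length <= k are untouched; the name is unchanged; quality (if
    any) retains the first k characters of each run.  Matching is on the
    (already uppercased) sequence, and N runs collapse like any base.
    """
    if k < 1:
        raise ConfigurationError(f"run length k must be >= 1, got {k}")
    seq = np.frombuffer(record.sequence.encode("latin-1"), dtype=np.uint8)
    mask = _keep_mask(seq, k)
    if mask.all():
        return record
    new_seq = seq[mask].tobytes().decode("latin-1")
    new_qual = None
    if record.quality is not None:
        q = np.frombuffer(record.quality.encode("latin-1"), dtype=np.uint8)
        new_qual = q[mask].tobytes().decode("latin-1")
    return ReadRecord(
        name=record.name, sequence=new_seq, quality=new_qual, comment=record.comment
    )


def compress_stream(
    stream: Iterable[ReadRecord], k: int = 1
) -> Iterator[ReadRecord]:
    if k < 1:
        raise ConfigurationError(f"run length k must be >= 1, got {k}")
    for rec in stream:
        yield homopolymer_compress(rec, k)


def hc_size_reduction(stream: Iterable[ReadRecord], k: int = 1) -> float:
    """Fractional base-count shrinkage of a dataset under homopolymer
    compression: 1 - (bases after) / (bases before).  Undefined (raises)
    on an empty stream."""
    before = after = 0
    for rec in stream:
        before += len(rec.sequence)
        after += len(homopolymer_compress(rec, k).sequence)
    if before == 0:
        raise ValueError("size reduction is undefined for an empty stream")
    return 1.0 - after / before


def run_length_decomposition(sequence: str) -> Iterator[Tuple[str, int]]:
    """(base, run length) pairs for the maximal runs of a sequence."""
    seq = np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)
    if seq.size == 0:
        return
    starts = np.empty(seq.size, dtype=bool)
    starts[0] = True
    np.not_equal(seq[1:], seq[:-1], out=starts[1:])
    idx = np.flatnonzero(starts)
    lengths = np.diff(np.append(idx, seq.size))
    for i, ln in zip(idx, lengths):
        yield chr(seq[i]), int(ln)
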