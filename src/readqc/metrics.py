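"""Per-read metrics and single-pass aggregate statistics.

Quality handling follows the Sanger convention: a per-base Phred score
Q = -10*log10(P) encoded as ASCII ``chr(Q + 33)`` for Q in 0..93.  The
per-read quality is the arithmetic mean of the integer Q values (the
"mean of the QUAL field" convention used for platform comparisons), not
the error-domain mean; :func:`mean_quality_error_domain` provides the
latter as an explicitly named alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import QualityEncodingError
from .records import ReadRecord, has_informative_quality

QUALITY_OFFSET = 33
MAX_QUALITY = 93

# Column order for base composition vectors.
BASE_ORDER = ("A", "C", "G", "T", "N", "other")

_ACGT = frozenset(b"ACGT")
_BASE_INDEX = np.full(256, 5, dtype=np.int64)  # default: "other"
for _i, _b in enumerate(b"ACGTN"):
    _BASE_INDEX[_b] = _i


def decode_quality(qual: str) -> np.ndarray:
    """Decode a Sanger quality string into integer Phred scores.

    Raises :class:`QualityEncodingError` naming the first offending
    position if any character falls outside ASCII 33-126.  No Phred+64 or
    Solexa auto-detection is attempted.
    """
    codes = np.frombuffer(qual.encode("latin-1"), dtype=np.uint8)
    bad = np.flatnonzero((codes < 33) | (codes > 126))
    if bad.size:
        pos = int(bad[0])
        raise QualityEncodingError(
            f"quality character {qual[pos]!r} at position {pos} outside "
            "Sanger range (ASCII 33-126)"
        )
    return codes.astype(np.int64) - QUALITY_OFFSET


def encode_quality(scores: Sequence[int]) -> str:
    """Inverse of :func:`decode_quality` on Q values in 0..93."""
    arr = np.asarray(scores, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > MAX_QUALITY):
        raise QualityEncodingError("Phred score outside 0-93")
    return (arr + QUALITY_OFFSET).astype(np.uint8).tobytes().decode("latin-1")


def phred_from_error(p: float) -> float:
    """Sanger Phred score -10*log10(p) for an error probability p in (0, 1]."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def error_from_phred(q: float) -> float:
    """Error probability 10**(-q/10)."""
    return 10.0 ** (-q / 10.0)


def mean_quality(scores: Sequence[int]) -> Optional[float]:
    """Arithmetic mean of integer Phred scores; ``None`` for an empty list."""
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size == 0:
        return None
    return float(arr.mean())


def mean_quality_error_domain(scores: Sequence[int]) -> Optional[float]:
    """Quality of the mean error probability, -10*log10(mean 10^(-Q/10)).

    Alternate aggregation that weights low-quality bases more heavily.
    Not used by default anywhere in the pipeline.
    """
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size == 0:
        return None
    return float(-10.0 * np.log10(np.mean(10.0 ** (-arr / 10.0))))


def round_half_up(q: float) -> int:
    """Round to nearest integer, ties away from zero-point-five upward."""
    return int(math.floor(q + 0.5))


@dataclass(slots=True)
class ReadSummary:
    """Per-read digest: everything the aggregate statistics need."""

    length: int
    base_counts: np.ndarray  # int64[6] in BASE_ORDER
    mean_q: Optional[float] = None
    median_q: Optional[float] = None

    @property
    def gc(self) -> Optional[float]:
        """GC fraction over unambiguous A/C/G/T calls; None if there are none."""
        a, c, g, t = (int(x) for x in self.base_counts[:4])
        denom = a + c + g + t
        if denom == 0:
            return None
        return (c + g) / denom


def summarize_read(record: ReadRecord, compute_median: bool = False) -> ReadSummary:
    """Digest one read: length, base composition, GC, mean (and optionally
    median) quality.

    Reads carrying only the Q0 placeholder quality written by FASTA
    up-conversion are treated as quality-absent.
    """
    seq = np.frombuffer(record.sequence.encode("latin-1"), dtype=np.uint8)
    counts = np.bincount(_BASE_INDEX[seq], minlength=6)
    mean_q = median_q = None
    if has_informative_quality(record):
        scores = decode_quality(record.quality)
        mean_q = float(scores.mean())
        if compute_median:
            median_q = float(np.median(scores))
    return ReadSummary(
        length=len(record.sequence),
        base_counts=counts.astype(np.int64),
        mean_q=mean_q,
        median_q=median_q,
    )


def nx(lengths: Sequence[int], x: float) -> int:
    """Nx read length: the smallest L such that reads of length >= L hold at
    least x% of the total bases.

    Computed by sorting descending and scanning the cumulative sum; on ties
    the first length reaching the target is returned.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("Nx is undefined for an empty length list")
    if not 0.0 < x <= 100.0:
        raise ValueError(f"x must be in (0, 100], got {x}")
    srt = np.sort(arr)[::-1]
    cs = np.cumsum(srt)
    total = int(cs[-1])
    if float(x).is_integer():
        # exact integer arithmetic: cs*100 >= x*total
        idx = int(np.searchsorted(cs * 100, int(x) * total, side="left"))
    else:
        idx = int(np.searchsorted(cs, x / 100.0 * total, side="left"))
    return int(srt[idx])


def nx_table(lengths: Sequence[int]) -> Dict[int, int]:
    """Nx for every integer x in 1..100 (empty dict for no reads)."""
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        return {}
    srt = np.sort(arr)[::-1]
    cs = np.cumsum(srt)
    total = int(cs[-1])
    xs = np.arange(1, 101, dtype=np.int64)
    idx = np.searchsorted(cs * 100, xs * total, side="left")
    return {int(x): int(srt[i]) for x, i in zip(xs, idx)}


def inverse_cumulative_curve(
    lengths: Sequence[int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse cumulative length distribution.

    Returns ``(thresholds, cumulative_bases)`` where ``cumulative_bases[i]``
    is the total bases contained in reads of length >= ``thresholds[i]``.
    Thresholds are 0 followed by the distinct read lengths in increasing
    order, so the curve starts at the dataset total and is monotone
    non-increasing.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        return np.array([0], dtype=np.int64), np.array([0], dtype=np.int64)
    uniq = np.unique(arr)  # ascending
    srt = np.sort(arr)
    # bases in reads >= t: suffix sums over the ascending sorted lengths
    suffix = np.concatenate([np.cumsum(srt[::-1])[::-1], [0]])
    first_ge = np.searchsorted(srt, uniq, side="left")
    values = suffix[first_ge]
    thresholds = np.concatenate([[0], uniq])
    curve = np.concatenate([[int(srt.sum())], values])
    return thresholds.astype(np.int64), curve.astype(np.int64)


def cumulative_bases_at(lengths: Sequence[int], threshold: int) -> int:
    """Total bases in reads at least ``threshold`` long."""
    arr = np.asarray(lengths, dtype=np.int64)
    return int(arr[arr >= threshold].sum())


@dataclass
class DatasetStats:
    """Aggregate statistics over a read stream.

    ``lengths`` is sorted descending (stable with respect to input order on
    ties) and ``mean_qs`` is aligned to it, with NaN marking quality-absent
    reads.  Everything else is derived.
    """

    lengths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mean_qs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    base_totals: np.ndarray = field(default_factory=lambda: np.zeros(6, dtype=np.int64))
    median_qs: Optional[np.ndarray] = None  # aligned to lengths when kept

    # -- scalar aggregates -------------------------------------------------
    @property
    def n_reads(self) -> int:
        return int(self.lengths.size)

    @property
    def total_bases(self) -> int:
        return int(self.lengths.sum())

    @property
    def length_min(self) -> Optional[int]:
        return int(self.lengths.min()) if self.n_reads else None

    @property
    def length_max(self) -> Optional[int]:
        return int(self.lengths.max()) if self.n_reads else None

    @property
    def length_mean(self) -> Optional[float]:
        return float(self.lengths.mean()) if self.n_reads else None

    @property
    def gc_overall(self) -> Optional[float]:
        a, c, g, t = (int(x) for x in self.base_totals[:4])
        denom = a + c + g + t
        return (c + g) / denom if denom else None

    @property
    def mean_q(self) -> Optional[float]:
        """Mean over per-read mean Q of quality-bearing reads."""
        q = self.mean_qs[~np.isnan(self.mean_qs)]
        return float(q.mean()) if q.size else None

    @property
    def n_quality_reads(self) -> int:
        return int((~np.isnan(self.mean_qs)).sum())

    # -- distributions -----------------------------------------------------
    @property
    def nx_table(self) -> Dict[int, int]:
        return nx_table(self.lengths)

    def nx(self, x: float) -> int:
        return nx(self.lengths, x)

    @property
    def n50(self) -> Optional[int]:
        return self.nx(50) if self.n_reads else None

    @property
    def q_histogram(self) -> np.ndarray:
        """Counts of per-read mean Q, rounded half-up, in integer bins 0..93."""
        hist = np.zeros(MAX_QUALITY + 1, dtype=np.int64)
        q = self.mean_qs[~np.isnan(self.mean_qs)]
        if q.size:
            bins = np.clip(np.floor(q + 0.5).astype(np.int64), 0, MAX_QUALITY)
            hist += np.bincount(bins, minlength=MAX_QUALITY + 1)
        return hist

    @property
    def lq_pairs(self) -> List[Tuple[int, Optional[float]]]:
        """(length, mean_q) per read, sorted by length descending."""
        return [
            (int(l), None if np.isnan(q) else float(q))
            for l, q in zip(self.lengths, self.mean_qs)
        ]

    def inverse_cumulative_curve(self) -> Tuple[np.ndarray, np.ndarray]:
        return inverse_cumulative_curve(self.lengths)

    # -- presentation ------------------------------------------------------
    def summary_table(self) -> List[Tuple[str, str]]:
        """Key/value rows for the machine-parseable text summary."""
        def fmt(v, nd=2):
            if v is None:
                return "NA"
            if isinstance(v, float):
                return f"{v:.{nd}f}"
            return str(v)

        return [
            ("n_reads", fmt(self.n_reads)),
            ("total_bases", fmt(self.total_bases)),
            ("min_length", fmt(self.length_min)),
            ("mean_length", fmt(self.length_mean)),
            ("max_length", fmt(self.length_max)),
            ("n50", fmt(self.n50)),
            ("gc", fmt(self.gc_overall, 4)),
            ("mean_q", fmt(self.mean_q)),
        ]

    def __eq__(self, other: object) -> bool:  # field-by-field, NaN-aware
        if not isinstance(other, DatasetStats):
            return NotImplemented
        if not np.array_equal(self.lengths, other.lengths):
            return False
        if not np.array_equal(self.mean_qs, other.mean_qs, equal_nan=True):
            return False
        if not np.array_equal(self.base_totals, other.base_totals):
            return False
        a, b = self.median_qs, other.median_qs
        if (a is None) != (b is None):
            return False
        return a is None or np.array_equal(a, b, equal_nan=True)


def aggregate(
    summaries: Iterable[ReadSummary], keep_median: bool = False
) -> DatasetStats:
    """Fold a stream of per-read summaries into dataset statistics.

    Single pass over the stream; memory is dominated by the retained
    per-read (length, Q) pairs, which the snapshot format also stores.
    """
    lengths: List[int] = []
    qs: List[float] = []
    medians: List[float] = []
    base_totals = np.zeros(6, dtype=np.int64)
    for s in summaries:
        lengths.append(s.length)
        qs.append(np.nan if s.mean_q is None else s.mean_q)
        if keep_median:
            medians.append(np.nan if s.median_q is None else s.median_q)
        base_totals += s.base_counts
    larr = np.asarray(lengths, dtype=np.int64)
    qarr = np.asarray(qs, dtype=np.float64)
    order = np.argsort(-larr, kind="stable")
    stats = DatasetStats(
        lengths=larr[order],
        mean_qs=qarr[order],
        base_totals=base_totals,
    )
    if keep_median:
        stats.median_qs = np.asarray(medians, dtype=np.float64)[order]
    return stats


def aggregate_records(
    records: Iterable[ReadRecord], keep_median: bool = False
) -> DatasetStats:
    """Convenience: summarize and aggregate a raw record stream."""
    return aggregate(
        (summarize_read(r, compute_median=keep_median) for r in records),
        keep_median=keep_median,
    )


def iter_summaries(
    records: Iterable[ReadRecord], compute_median: bool = False
) -> Iterator[ReadSummary]:
    for r in records:
        yield summarize_read(r, compute_median=compute_median)
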