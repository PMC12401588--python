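"""Composable stream filters: length/quality bounds, name lists, sampling,
and quality capping.

All numeric bounds are inclusive.  The quality criterion applies to the
per-read mean Q (the HiFi "average quality >= Q20" convention), not the
minimum per-base Q.  Filters are one conjunction evaluated in a fixed
order — name lists, length, quality, sampling — so per-stage rejection
counts are well defined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Set, Union

import numpy as np

from .errors import ConfigurationError
from .metrics import MAX_QUALITY, QUALITY_OFFSET, decode_quality
from .records import ReadRecord, has_informative_quality

PathLike = Union[str, Path]


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of read-retention criteria; unset fields are no-ops."""

    min_length: Optional[int] = None
    max_length: Optional[int] = None
    min_q: Optional[float] = None
    max_q: Optional[float] = None
    include_names: Optional[frozenset] = None
    exclude_names: Optional[frozenset] = None
    sample_fraction: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ConfigurationError("min_length exceeds max_length")
        if (
            self.min_q is not None
            and self.max_q is not None
            and self.min_q > self.max_q
        ):
            raise ConfigurationError("min_q exceeds max_q")
        if self.sample_fraction is not None and not 0.0 < self.sample_fraction <= 1.0:
            raise ConfigurationError("sample_fraction must be in (0, 1]")
        if self.include_names and self.exclude_names:
            both = set(self.include_names) & set(self.exclude_names)
            if both:
                raise ConfigurationError(
                    f"names in both include and exclude lists: {sorted(both)[:5]}"
                )

    @property
    def is_identity(self) -> bool:
        return self == FilterSpec()


#: HiFi convention: keep reads whose mean quality is at least Q20.
HIFI_PRESET = FilterSpec(min_q=20)
#: Ultralong convention: keep reads over 100 kb.
UL_PRESET = FilterSpec(min_length=100_000)
#: Revio convention: per-base qualities capped at Q40 (see cap_quality).
REVIO_CAP = 40

PRESETS = {"hifi": HIFI_PRESET, "ul": UL_PRESET}


def load_name_list(path: PathLike) -> frozenset:
    """Read a name-per-line list; text after the first whitespace is ignored
    to match the read-identity convention."""
    names = set()
    with open(path) as fh:
        for line in fh:
            token = line.split()[0] if line.split() else ""
            if token:
                names.add(token)
    return frozenset(names)


def read_mean_quality(record: ReadRecord) -> Optional[float]:
    if not has_informative_quality(record):
        return None
    return float(decode_quality(record.quality).mean())


def apply_filter(
    stream: Iterable[ReadRecord],
    spec: FilterSpec,
    counts: Optional[Counter] = None,
) -> Iterator[ReadRecord]:
    """Yield reads passing every criterion in ``spec``.

    Quality-absent reads fail any quality criterion; their number is
    tracked under ``counts['no_quality']`` when a counter is supplied.
    Pass a Counter to collect per-stage rejection tallies.
    """
    if counts is None:
        counts = Counter()
    rng = (
        np.random.default_rng(spec.seed)
        if spec.sample_fraction is not None
        else None
    )
    has_q_criterion = spec.min_q is not None or spec.max_q is not None
    for rec in stream:
        counts["input"] += 1
        if spec.include_names is not None and rec.name not in spec.include_names:
            counts["rejected_name"] += 1
            continue
        if spec.exclude_names is not None and rec.name in spec.exclude_names:
            counts["rejected_name"] += 1
            continue
        n = len(rec.sequence)
        if spec.min_length is not None and n < spec.min_length:
            counts["rejected_length"] += 1
            continue
        if spec.max_length is not None and n > spec.max_length:
            counts["rejected_length"] += 1
            continue
        if has_q_criterion:
            mq = read_mean_quality(rec)
            if mq is None:
                counts["no_quality"] += 1
                counts["rejected_quality"] += 1
                continue
            if spec.min_q is not None and mq < spec.min_q:
                counts["rejected_quality"] += 1
                continue
            if spec.max_q is not None and mq > spec.max_q:
                counts["rejected_quality"] += 1
                continue
        if rng is not None and rng.random() >= spec.sample_fraction:
            counts["rejected_sampling"] += 1
            continue
        counts["passed"] += 1
        yield rec


def sample_reads(
    stream: Iterable[ReadRecord], fraction: float, seed: int
) -> Iterator[ReadRecord]:
    """Bernoulli downsampling: each read kept independently with
    probability ``fraction``; deterministic under ``seed``; preserves
    relative order; single pass."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    for rec in stream:
        if rng.random() < fraction:
            yield rec


def cap_quality(
    stream: Iterable[ReadRecord], cap: int
) -> Iterator[ReadRecord]:
    """Clamp per-base quality at ``cap`` (Revio-style binning cap; the
    'revio' preset uses Q40)."""
    if not 0 <= cap <= MAX_QUALITY:
        raise ConfigurationError(f"cap must be in 0..{MAX_QUALITY}, got {cap}")
    cap_byte = cap + QUALITY_OFFSET
    for rec in stream:
        if rec.quality is None:
            yield rec
            continue
        arr = np.frombuffer(rec.quality.encode("latin-1"), dtype=np.uint8)
        if arr.size and int(arr.max()) > cap_byte:
            clamped = np.minimum(arr, cap_byte)
            rec = replace_quality(rec, clamped.tobytes().decode("latin-1"))
        yield rec


def replace_quality(rec: ReadRecord, quality: str) -> ReadRecord:
    return ReadRecord(
        name=rec.name, sequence=rec.sequence, quality=quality, comment=rec.comment
    )


# ---------------------------------------------------------------------------
# mini-expression parser for --filter "l>10000 q>20"

_FIELDS = {"l": "length", "q": "quality"}
_OPS = (">=", "<=", ">", "<", "=")


def parse_filter_expression(expr: str, base: FilterSpec = FilterSpec()) -> FilterSpec:
    """Parse whitespace-separated terms like ``l>10000`` or ``q<=30`` into a
    FilterSpec.  All bounds are inclusive, so ``>`` and ``>=`` are synonyms
    (documented convention)."""
    spec = base
    for term in expr.split():
        for op in _OPS:
            if op in term:
                fld, _, val = term.partition(op)
                break
        else:
            raise ConfigurationError(f"cannot parse filter term {term!r}")
        fld = fld.strip().lower()
        if fld not in _FIELDS:
            raise ConfigurationError(
                f"unknown filter field {fld!r} (expected 'l' or 'q')"
            )
        try:
            num = float(val)
        except ValueError as exc:
            raise ConfigurationError(f"bad number in filter term {term!r}") from exc
        if fld == "l":
            num = int(num)
            if op in (">", ">="):
                spec = replace(spec, min_length=num)
            elif op in ("<", "<="):
                spec = replace(spec, max_length=num)
            else:
                spec = replace(spec, min_length=num, max_length=num)
        else:
            if op in (">", ">="):
                spec = replace(spec, min_q=num)
            elif op in ("<", "<="):
                spec = replace(spec, max_q=num)
            else:
                spec = replace(spec, min_q=num, max_q=num)
    return spec
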