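"""Shared fixtures and the independent brute-force statistics oracle.

The oracle deliberately avoids the package's aggregation code paths: it is
a naive two-pass computation over plain Python lists, used to validate the
streaming implementation.
"""

from __future__ import annotations

import math
import random
from typing import Dict, List, Optional

import numpy as np
import pytest

from readqc.records import ReadRecord

BASES = "ACGT"


# ---------------------------------------------------------------------------
# naive oracle


def naive_mean_q(quality: Optional[str]) -> Optional[float]:
    if quality is None or quality == "" or set(quality) == {"!"}:
        return None
    scores = [ord(c) - 33 for c in quality]
    return sum(scores) / len(scores)


def naive_nx(lengths: List[int], x: float) -> int:
    """Brute force over all cut points of the descending-sorted lengths."""
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    running = 0
    for length in srt:
        running += length
        if running * 100 >= x * total:
            return length
    return srt[-1]


def naive_stats(records: List[ReadRecord]) -> Dict:
    """Two-pass aggregation with plain Python, independent of the package."""
    lengths = [len(r.sequence) for r in records]
    mean_qs = [naive_mean_q(r.quality) for r in records]
    base_totals = {b: 0 for b in "ACGTN"}
    other = 0
    for r in records:
        for ch in r.sequence:
            if ch in base_totals:
                base_totals[ch] += 1
            else:
                other += 1
    acgt = sum(base_totals[b] for b in "ACGT")
    q_present = [q for q in mean_qs if q is not None]
    hist = [0] * 94
    for q in q_present:
        hist[min(93, max(0, math.floor(q + 0.5)))] += 1
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    return {
        "n_reads": len(records),
        "total_bases": sum(lengths),
        "length_min": min(lengths) if lengths else None,
        "length_max": max(lengths) if lengths else None,
        "length_mean": sum(lengths) / len(lengths) if lengths else None,
        "gc_overall": (base_totals["G"] + base_totals["C"]) / acgt if acgt else None,
        "mean_q": sum(q_present) / len(q_present) if q_present else None,
        "n_quality_reads": len(q_present),
        "base_totals": [base_totals[b] for b in "ACGTN"] + [other],
        "q_histogram": hist,
        "lengths_sorted": [lengths[i] for i in order],
        "mean_qs_sorted": [mean_qs[i] for i in order],
        "nx_table": {x: naive_nx(lengths, x) for x in range(1, 101)} if lengths else {},
    }


def random_records(
    rng: random.Random,
    n: int,
    max_len: int = 300,
    p_quality: float = 0.7,
    p_placeholder: float = 0.05,
    alphabet: str = BASES + "N" + "RYKM",
) -> List[ReadRecord]:
    """Messy random reads: varied alphabet, quality sometimes absent or a
    pure Q0 placeholder, zero-length reads possible."""
    records = []
    for i in range(n):
        length = rng.randint(0, max_len)
        seq = "".join(rng.choice(alphabet) for _ in range(length))
        qual = None
        u = rng.random()
        if u < p_placeholder:
            qual = "!" * length
        elif u < p_quality:
            qual = "".join(chr(rng.randint(33, 126)) for _ in range(length))
        records.append(ReadRecord(name=f"r{i}", sequence=seq, quality=qual))
    return records


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def nprng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_records() -> List[ReadRecord]:
    return [
        ReadRecord("r1", "ACGTACGT", "IIIIIIII"),
        ReadRecord("r2", "GGGGCCCCAAAA", None),
        ReadRecord("r3", "ACGTNNNACA", "55555?????"),
        ReadRecord("r4", "", None),
        ReadRecord("r5", "TTTT", "!!!!"),  # placeholder quality
    ]


@pytest.fixture
def fastq_path(tmp_path):
    """A tiny FASTQ file on disk."""
    p = tmp_path / "reads.fastq"
    p.write_text(
        "@r1 first read\nACGT\n+\nIIII\n"
        "@r2\nGGCC\n+\n!!!!\n"
        "@r3\nACGTACGTAC\n+\n5?5?5?5?5?\n"
    )
    return p
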