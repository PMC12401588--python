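"""Filter reads by quality and length, then convert FASTQ to BAM.

Keeps only reads with mean quality >= Q30 and length >= 18 kb, and
writes the survivors as an unaligned BAM — a smaller, index-capable
container for the same reads.
"""

import tempfile
from pathlib import Path

from readqc import (
    FilterSpec, apply_filter, open_reads, simulate_reads, write_reads,
)
from collections import Counter

tmp = Path(tempfile.mkdtemp())
fq = tmp / "mixed.fastq"
simulate_reads("hifi", n=400, seed=3, out=fq)

spec = FilterSpec(min_q=30, min_length=18_000)
counts = Counter()
kept = apply_filter(open_reads([fq]), spec, counts=counts)
n = write_reads(kept, tmp / "filtered.bam")

print(f"input reads:     {counts['input']}")
print(f"rejected length: {counts['rejected_length']}")
print(f"rejected quality:{counts['rejected_quality']}")
print(f"written to BAM:  {n}")
print(f"FASTQ size: {fq.stat().st_size}  BAM size: "
      f"{(tmp / 'filtered.bam').stat().st_size}")
# The BAM holds fewer reads than the FASTQ (the filter) and compresses
# the remainder with BGZF.
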