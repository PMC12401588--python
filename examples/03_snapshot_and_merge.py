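"""Write per-file snapshots, merge them, and recall statistics without
touching the original reads.

Each .rd snapshot stores sorted per-read lengths, quantized mean
qualities, base totals and the md5 provenance of its inputs — kilobytes
instead of the megabytes of raw reads — and merging snapshots is
equivalent to evaluating the concatenated inputs.
"""

import tempfile
from pathlib import Path

from readqc import (
    SourceInfo, aggregate_records, open_reads, simulate_reads,
    snapshot_merge, snapshot_read, snapshot_write,
)

tmp = Path(tempfile.mkdtemp())
rd_paths = []
for i, (profile, n) in enumerate([("hifi", 300), ("ont_ul", 300)]):
    reads = tmp / f"run{i}.fastq"
    simulate_reads(profile, n=n, seed=i, out=reads)
    stats = aggregate_records(open_reads([reads]))
    rd = tmp / f"run{i}.rd"
    snapshot_write(stats, [SourceInfo.from_file(reads, stats.n_reads)], rd)
    print(f"{reads.name}: {reads.stat().st_size:>9} bytes -> "
          f"{rd.name}: {rd.stat().st_size} bytes")
    rd_paths.append(rd)

merged = tmp / "all.rd"
snapshot_merge(rd_paths, merged)
stats, header = snapshot_read(merged)
print(f"\nmerged snapshot: {stats.n_reads} reads, "
      f"{stats.total_bases / 1e6:.1f} Mbp, N50 {stats.n50} bp")
for src in header.sources:
    print(f"  source {src.path} md5 {src.md5_hex} ({src.read_count} reads)")
# The merged statistics equal what a single run over both FASTQs would
# report; the md5s tie every number back to its input file.
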