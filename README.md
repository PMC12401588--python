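# readqc

Streaming evaluation of sequencing-read datasets: per-read and aggregate
statistics, filtering, downsampling, homopolymer compression, lossless
interconversion of read formats, and tiny mergeable binary "snapshot"
files from which reports are regenerated without the raw data.

`readqc` is for anyone who handles read files at scale — sequencing
cores, assembly groups, archive curators — and needs fast answers to
"how many reads, how long, how good?" across FASTA, FASTQ (plain or
gzip), SAM, BAM and CRAM, including mixed-format runs, without writing
per-format glue.

## What it computes

For each read, length, base composition, GC fraction and the mean
quality over the Phred scores `Q = -10·log10(P)` carried in Sanger
encoding (ASCII 33–126 ↔ Q0–Q93). Over a dataset, in one O(total bases)
pass: read/base counts, length extremes and mean, the quality histogram,
per-read (length, Q) pairs, and the full Nx table, where

> **Nx** is the smallest read length *L* such that reads of length ≥ *L*
> contain at least *x*% of the total bases (N50 is *x* = 50),

plus the inverse cumulative length distribution — total bases in reads
at least *t* long — which reads off coverage above any length cutoff.

Statistics can be persisted to a `.rd` **snapshot**: a binary file with
a provenance header (every input's path, size, md5 and read count), the
uncompressed payload size as a uint64, and a gzip-compressed payload of
sorted lengths (adaptive 1/2/8-byte integers) and 1-byte quantized
qualities. Snapshots are typically thousands of times smaller than the
gzipped reads, merge in milliseconds as if computed on the concatenated
inputs, and by construction cannot reconstruct sequences.

## Worked example

```sh
$ readqc simulate --profile hifi --n 500 --seed 7 -o hifi.fastq.gz
wrote 500 hifi reads to hifi.fastq.gz
$ readqc hifi.fastq.gz -s hifi.rd
n_reads 500
total_bases     10218432
min_length      14099
mean_length     20436.86
max_length      28416
n50     20519
gc      0.4998
mean_q  30.04
```

500 synthetic HiFi-like reads hold ~10.2 Mbp; half the bases are in
reads of at least 20 519 bp (N50), base composition is balanced
(GC 0.4998), and the average per-read quality is ~Q30, i.e. a mean base
error around 10⁻³. The same summary is recalled from the 2 kB snapshot
alone with `readqc stats hifi.rd`, and `readqc report hifi.rd -o
report.html` renders the length/quality panels from it without the
FASTQ.

Filtering and conversion compose on the same streams, e.g. keep
HiFi-grade reads (`mean Q ≥ 20`) over 10 kb and store them as unaligned
BAM:

```sh
readqc hifi.fastq.gz --preset hifi --filter "l>10000" -o filtered.bam
```

The `examples/` directory holds runnable scripts for each capability
(summary statistics, filtering + conversion, snapshots + merging,
reports, homopolymer compression); each prints the numbers it computes
and what they mean. The library API mirrors the CLI one-to-one
(`open_reads`, `apply_filter`, `aggregate_records`, `snapshot_write`,
`render_report`, ...).

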