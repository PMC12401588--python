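# Methods

## Model of a read and its quality

A read is a named sequence over `{A,C,G,T,N, IUPAC}` with an optional
Sanger-encoded quality string (`chr(Q+33)`, Q ∈ 0..93) of equal length.
The read identity is the header up to the first whitespace; the
remainder is retained for FASTA/FASTQ re-emission but is not
representable in SAM-family records. Sequences are uppercased on ingest
so composition counting is case-insensitive; the original case is not
preserved through conversion.

Per-read quality is the **arithmetic mean of the integer Phred values**
(the "mean of the QUAL field" convention used when comparing platforms),
not the quality of the mean error probability. The error-domain
aggregate `-10·log10(mean 10^(-Q/10))` is exposed as
`mean_quality_error_domain` for users who want error-weighted means; it
is never used implicitly. Rounding for histogram bins and snapshot
storage is half-up to the nearest integer in 0..93.

Reads whose quality is entirely `'!'` (Q0) are treated as
quality-absent: that is the placeholder written when quality-less input
is up-converted to FASTQ/BAM/CRAM, and counting it would drag quality
aggregates to zero. The cost is that a genuine all-Q0 read (which no
platform emits) is indistinguishable from a placeholder.

## Streaming aggregation

Aggregation folds per-read summaries in a single pass; memory is
O(n_reads) for the retained (length, mean-Q) pairs — the same payload
the snapshot stores — plus constants. Nx is computed by sorting lengths
descending and scanning the cumulative sum with integer arithmetic
(`100·cumsum ≥ x·total`), returning the first length that reaches the
target; ties therefore resolve to the earlier (longer-side) cut, and
Nx is monotone non-increasing in x with Nx(100) = min length. GC is
defined over unambiguous A/C/G/T only; N and other ambiguity codes are
excluded from the denominator. The inverse cumulative curve is reported
at thresholds {0} ∪ {distinct lengths}; between listed thresholds the
function is constant on left-open intervals, so plots use a "pre" step.

## Filtering, sampling, capping

Filters form one conjunction evaluated in a fixed order — name lists,
length, quality, sampling — so per-stage rejection counts are well
defined. All numeric bounds are inclusive, including terms written with
`>` in `--filter` mini-expressions (`q>20` keeps mean Q = 20.0); the
quality criterion applies to the per-read mean, matching the HiFi
"average quality ≥ Q20" convention, and quality-absent reads fail any
quality criterion (counted, warned). Presets: `hifi` (min mean Q20),
`ul` (min length 100 kb), `revio` (per-base Q capped at 40).

Downsampling is single-pass Bernoulli: each read is kept independently
with probability f under a seeded generator, preserving order and
streaming memory. The retained count is Binomial(n, f), not exact-count;
an exact-fraction reservoir mode would need buffering and is noted as an
extension, not implemented. Whether upstream tools sample exactly is not
asserted here.

## Homopolymer compression

Every maximal run of one base longer than k is replaced by exactly k
copies, in one linear pass (vectorised run-boundary detection, constant
auxiliary state). Quality keeps the first k characters of each run —
deterministic and order-preserving, with no arithmetic on Phred values.
N runs collapse like any base, which can be surprising when N-gaps are
long; this is deliberate and documented rather than special-cased. The
operation is idempotent and never lengthens a read; on i.i.d. uniform
sequence the expected shrinkage at k=1 is 25%, since a base repeats its
predecessor with probability 1/4.

## Snapshot format

The `.rd` layout is this package's own (magic `RDQC`, version,
provenance entries with md5-16 digests of the on-disk bytes, a uint64
uncompressed payload size, then a gzip level-6 payload with zeroed mtime
for byte-determinism). Lengths are stored sorted descending in the
smallest of {1, 2, 8}-byte little-endian integers that holds the
maximum — the 2-byte tier covers short-read data, the 8-byte tier
anything longer; there is deliberately no 4-byte tier. Mean qualities
are 1 byte per read (0–93; 255 = absent), so a snapshot round trip
reproduces lengths, base totals and provenance exactly and per-read Q to
±0.5. Merging concatenates arrays, re-sorts, sums base totals, and
re-chooses the width, which makes it associative and commutative at the
statistics level; duplicate source md5s are flagged as possible double
counting but not refused, since re-merging overlapping snapshot sets is
sometimes intended. Sequence data never enters the payload, so reads
cannot be reconstructed.

## Formats

Detection is content-based only: gzip by `1F 8B` (then the decompressed
head is sniffed), BAM by the BGZF-wrapped `BAM\x01` magic, CRAM by its
magic, `>` for FASTA, `@` for FASTQ unless the line is a tab-delimited
SAM header; headerless SAM is recognised by ≥ 11 tab-separated fields.
A zero-byte file is reported as an empty FASTA stream, flagged. In
SAM/BAM/CRAM input, secondary (0x100) and supplementary (0x800) records
are skipped so each physical read appears once; `QUAL *` becomes absent
quality. Output SAM-family records are unaligned (FLAG 4); CRAM is
written in no-reference mode since unaligned reads have no reference to
delta against. Gzip output zeroes the mtime and omits the filename field
so identical content gives identical bytes.

## Synthetic data generator

The generator emulates the length/quality *shapes* of common platforms,
not their error processes: lognormal lengths (mode-parameterised, so the
stated mode is the density peak), two-component lognormal mixtures for
the dispersed bimodal ultralong case, truncated-normal per-read mean
qualities with per-base integer jitter (sd 2), and an optional
length–quality coupling for the HiFi profile (mean Q decreases ~2.5 per
length z-score, reflecting fewer consensus passes on longer reads).
Defaults: `hifi` mode 20 kb (σ=0.13), mean Q30 in a Q20–40 window;
`ont_ul` length peaks at 500 bp and 40 kb (weights 0.5/0.5), quality
modes Q7/Q17 (weights 0.55/0.45); `illumina` constant 150 bp with
quality capped at Q39 clip-style, so the mode sits at the cap as it does
on binned platform output; `clr` long-tailed around 15 kb at ~Q9 —
values chosen to match the platform behaviours the profiles emulate.
Sequences are i.i.d. uniform A/C/G/T with an optional Markov repeat
probability for homopolymer experiments. Everything is deterministic
under a seed.

What the generator does *not* model — adapter/chimera artefacts,
position-dependent error, real base-caller quality calibration,
duplicated reads — bounds what passing tests mean: they validate the
statistics, formats and file machinery on realistic shapes, not
platform fidelity.

## Numerical and design choices

- Nx uses integer cumulative-sum comparisons; no floating-point
  thresholds for integer x.
- Per-read median quality is optional (it needs the per-base vector),
  stored in snapshots when computed, required by no report.
- Degenerate inputs: empty streams aggregate to zeros with an empty Nx
  table; Nx and homopolymer shrinkage on empty input raise rather than
  return a sentinel; zero-length reads are representable and counted.
- Report density estimation uses Gaussian KDE with the default
  rule-of-thumb bandwidth; length histograms use Freedman–Diaconis bins
  (clamped to 5–400). Datasets too degenerate for a KDE fall back to a
  scatter layer.
- Interactive reports are plain self-contained HTML: matplotlib SVG
  with per-dataset artist ids plus ~40 lines of vanilla JS for dataset
  toggling and canvas-based PNG export. PDF is static-only.
- Test and acceptance problem sizes (10³–10⁵ reads; short reads for
  round-trip volume, summary-only sampling for the 10⁵-read scaling
  experiment) are chosen so distribution-level checks have comfortable
  statistical margins while the suite stays quick on a laptop.

## Known limitations

Paired-end reads are processed as independent reads; BED/coordinate
include-exclude lists are not interpretable for unaligned reads and are
not supported (name lists are); CRAM efficiency tuning against a
reference is out of scope; snapshots from other tools' binary summary
formats are not readable — the `.rd` layout here is documented above
and versioned, but compatibility with any external layout is not
claimed.
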