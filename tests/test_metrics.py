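"""Per-read metrics and streaming aggregation against independent oracles."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readqc import metrics
from readqc.errors import QualityEncodingError
from readqc.records import ReadRecord

from conftest import naive_nx, naive_stats, random_records


class TestQualityDecoding:
    @pytest.mark.parametrize(
        "qual,expected",
        [("~", [93]), ("!", [0]), ("5?", [20, 30]), ("I", [40])],
    )
    def test_sanger_decoding(self, qual, expected):
        assert metrics.decode_quality(qual).tolist() == expected

    def test_out_of_range_character_is_rejected_with_position(self):
        with pytest.raises(QualityEncodingError, match="position 1"):
            metrics.decode_quality("I\x1fI")

    @given(st.lists(st.integers(0, 93), max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_decode_encode_identity(self, scores):
        assert metrics.decode_quality(metrics.encode_quality(scores)).tolist() == scores

    @pytest.mark.parametrize("p,q", [(1.0, 0.0), (0.01, 20.0), (0.001, 30.0)])
    def test_phred_from_error(self, p, q):
        assert metrics.phred_from_error(p) == pytest.approx(q, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, -0.5, 1.5])
    def test_phred_from_error_domain(self, p):
        with pytest.raises(ValueError):
            metrics.phred_from_error(p)

    @pytest.mark.parametrize(
        "scores,expected",
        [([20, 30], 25.0), ([7], 7.0), ([0, 0, 0, 93], 23.25)],
    )
    def test_mean_quality(self, scores, expected):
        assert metrics.mean_quality(scores) == pytest.approx(expected)

    def test_mean_quality_empty_is_absent_not_zero(self):
        assert metrics.mean_quality([]) is None

    def test_error_domain_mean_weights_low_quality(self):
        # one Q0 base among Q40s dominates the error-probability mean
        plain = metrics.mean_quality([0, 40, 40, 40])
        errdom = metrics.mean_quality_error_domain([0, 40, 40, 40])
        assert errdom < plain
        assert errdom == pytest.approx(-10 * math.log10((1 + 3e-4) / 4))


class TestSummarizeRead:
    def test_basic_read(self):
        s = metrics.summarize_read(ReadRecord("r1", "ACGT", "IIII"))
        assert s.length == 4
        assert s.gc == pytest.approx(0.5)
        assert s.mean_q == pytest.approx(40.0)

    def test_all_n_read_has_no_gc(self):
        s = metrics.summarize_read(ReadRecord("r2", "NNNN"))
        assert s.length == 4
        assert s.gc is None
        assert s.base_counts[4] == 4

    def test_gc_of_pure_gc_read(self):
        assert metrics.summarize_read(ReadRecord("r3", "GGCC")).gc == 1.0

    def test_base_counts_sum_to_length(self):
        s = metrics.summarize_read(ReadRecord("r", "ACGTNRYKMACGT"))
        assert int(s.base_counts.sum()) == 13

    def test_iupac_codes_excluded_from_gc_denominator(self):
        # R/Y ambiguity codes count as "other", not in GC
        s = metrics.summarize_read(ReadRecord("r", "GCRY"))
        assert s.gc == 1.0
        assert s.base_counts[5] == 2

    def test_placeholder_quality_treated_as_absent(self):
        s = metrics.summarize_read(ReadRecord("r", "ACGT", "!!!!"))
        assert s.mean_q is None

    def test_genuine_quality_including_q0_bases_kept(self):
        s = metrics.summarize_read(ReadRecord("r", "ACGT", "!!I!"))
        assert s.mean_q == pytest.approx(10.0)

    def test_median_optional(self):
        s = metrics.summarize_read(ReadRecord("r", "ACG", "5?5"), compute_median=True)
        assert s.median_q == pytest.approx(20.0)


class TestNx:
    @pytest.mark.parametrize(
        "lengths,x,expected",
        [([10, 20, 30], 50, 30), ([5, 5, 5, 5], 50, 5), ([100], 1, 100),
         ([100], 100, 100)],
    )
    def test_examples(self, lengths, x, expected):
        assert metrics.nx(lengths, x) == expected

    def test_empty_is_signalled(self):
        with pytest.raises(ValueError):
            metrics.nx([], 50)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=100))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_brute_force_and_is_monotone(self, lengths):
        values = [metrics.nx(lengths, x) for x in range(1, 101)]
        assert values == [naive_nx(lengths, x) for x in range(1, 101)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[-1] == min(lengths)

    def test_nx_table_matches_pointwise(self):
        lengths = [3, 14, 15, 92, 65, 35]
        table = metrics.nx_table(lengths)
        assert table == {x: metrics.nx(lengths, x) for x in range(1, 101)}


class TestInverseCumulative:
    def test_two_read_example(self):
        assert metrics.cumulative_bases_at([10, 20], 15) == 20
        assert metrics.cumulative_bases_at([10, 20], 0) == 30

    def test_curve_starts_at_total_and_decreases(self, rng):
        lengths = [rng.randint(1, 5000) for _ in range(500)]
        thresholds, curve = metrics.inverse_cumulative_curve(lengths)
        assert thresholds[0] == 0 and curve[0] == sum(lengths)
        assert all(a >= b for a, b in zip(curve, curve[1:]))

    def test_curve_matches_filter_and_sum_oracle(self, rng):
        lengths = [rng.randint(1, 2000) for _ in range(500)]
        thresholds, curve = metrics.inverse_cumulative_curve(lengths)
        for t, v in zip(thresholds.tolist(), curve.tolist()):
            assert v == sum(l for l in lengths if l >= t)


class TestAggregate:
    def test_basic_lengths(self):
        recs = [ReadRecord(f"r{i}", "A" * n) for i, n in enumerate([10, 20, 30])]
        stats = metrics.aggregate_records(recs)
        assert stats.n_reads == 3
        assert stats.total_bases == 60
        assert stats.length_mean == pytest.approx(20.0)

    def test_empty_stream(self):
        stats = metrics.aggregate([])
        assert stats.n_reads == 0
        assert stats.total_bases == 0
        assert stats.nx_table == {}
        assert stats.length_min is None and stats.mean_q is None

    def test_streaming_equals_naive_oracle(self, rng):
        records = random_records(rng, 1000)
        stats = metrics.aggregate_records(records)
        expected = naive_stats(records)
        assert stats.n_reads == expected["n_reads"]
        assert stats.total_bases == expected["total_bases"]
        assert stats.base_totals.tolist() == expected["base_totals"]
        assert stats.q_histogram.tolist() == expected["q_histogram"]
        assert stats.lengths.tolist() == expected["lengths_sorted"]
        assert stats.gc_overall == pytest.approx(expected["gc_overall"], abs=1e-9)
        assert stats.mean_q == pytest.approx(expected["mean_q"], abs=1e-9)
        assert stats.nx_table == expected["nx_table"]

    def test_quality_histogram_conservation(self, rng):
        records = random_records(rng, 500)
        stats = metrics.aggregate_records(records)
        assert int(stats.q_histogram.sum()) == stats.n_quality_reads
        assert stats.total_bases == int(stats.base_totals.sum())

    def test_lq_pairs_sorted_descending_and_complete(self, rng):
        records = random_records(rng, 200)
        stats = metrics.aggregate_records(records)
        pairs = stats.lq_pairs
        assert len(pairs) == stats.n_reads
        assert all(a[0] >= b[0] for a, b in zip(pairs, pairs[1:]))
        assert stats.total_bases == sum(l for l, _ in pairs)

    def test_summary_table_is_machine_parseable(self, rng):
        stats = metrics.aggregate_records(random_records(rng, 50))
        table = stats.summary_table()
        keys = [k for k, _ in table]
        assert keys == ["n_reads", "total_bases", "min_length", "mean_length",
                        "max_length", "n50", "gc", "mean_q"]
        assert all(isinstance(v, str) for _, v in table)


def test_aggregate_against_seqkit_cross_check(tmp_path):
    """Independent cross-check of N50/total/count against seqkit stats."""
    import shutil
    import subprocess

    if shutil.which("seqkit") is None:
        pytest.skip("seqkit not on PATH")
    from readqc import simulate, formats

    path = tmp_path / "reads.fastq"
    simulate.simulate_reads("ont_ul", 300, 11, path)
    stats = metrics.aggregate_records(formats.read_file(path))
    out = subprocess.run(
        ["seqkit", "stats", "-a", "-T", str(path)],
        capture_output=True, text=True, check=True,
    ).stdout.splitlines()
    header = out[0].split("\t")
    row = dict(zip(header, out[1].split("\t")))
    assert int(row["num_seqs"]) == stats.n_reads
    assert int(row["sum_len"]) == stats.total_bases
    assert int(row["N50"]) == stats.n50
    assert int(row["min_len"]) == stats.length_min
    assert int(row["max_len"]) == stats.length_max
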