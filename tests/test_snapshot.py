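"""Snapshot (.rd) serialization: round trips, merging, corruption handling."""

import gzip
import struct

import numpy as np
import pytest

from readqc import formats, metrics, simulate, snapshot
from readqc.errors import (
    CorruptSnapshotError,
    NotASnapshotError,
    SnapshotVersionError,
)
from readqc.records import ReadRecord
from readqc.snapshot import (
    SourceInfo,
    choose_width,
    md5_file,
    merge_stats,
    quantized,
    snapshot_merge,
    snapshot_read,
    snapshot_write,
)

from conftest import random_records


def _stats_for(records):
    return metrics.aggregate_records(records)


@pytest.fixture
def hifi_stats(nprng):
    return metrics.aggregate(simulate.generate_summaries("hifi", 500, 77))


class TestMd5:
    def test_empty_file_standard_digest(self, tmp_path):
        p = tmp_path / "empty"
        p.touch()
        assert md5_file(p).hex() == "d41d8cd98f00b204e9800998ecf8427e"

    def test_rfc1321_vector(self, tmp_path):
        p = tmp_path / "abc"
        p.write_bytes(b"abc")
        assert md5_file(p).hex() == "900150983cd24fb0d6963f7d28e17f72"

    def test_stable_across_calls(self, tmp_path):
        p = tmp_path / "f"
        p.write_bytes(b"some read data")
        assert md5_file(p) == md5_file(p)


class TestWidthRule:
    @pytest.mark.parametrize(
        "max_len,width", [(0, 1), (200, 1), (255, 1), (256, 2), (65_535, 2),
                          (65_536, 8), (70_000, 8), (10**12, 8)]
    )
    def test_smallest_sufficient_width(self, max_len, width):
        assert choose_width(max_len) == width


class TestRoundTrip:
    def test_round_trip_identity_on_stored_fields(self, rng, tmp_path):
        stats = _stats_for(random_records(rng, 2000))
        out = tmp_path / "s.rd"
        snapshot_write(stats, [], out)
        back, header = snapshot_read(out)
        assert back == quantized(stats)
        assert header.payload_size > 0

    def test_round_trip_preserves_aggregates_within_quantization(self, rng, tmp_path):
        records = random_records(rng, 1000)
        stats = _stats_for(records)
        out = tmp_path / "s.rd"
        snapshot_write(stats, [], out)
        back, _ = snapshot_read(out)
        assert back.n_reads == stats.n_reads
        assert back.total_bases == stats.total_bases
        assert back.nx_table == stats.nx_table
        assert back.base_totals.tolist() == stats.base_totals.tolist()
        assert back.gc_overall == pytest.approx(stats.gc_overall)
        # per-read mean Q stored as rounded integers
        assert back.mean_q == pytest.approx(stats.mean_q, abs=0.5)
        assert back.q_histogram.tolist() == stats.q_histogram.tolist()

    def test_empty_dataset_round_trip(self, tmp_path):
        out = tmp_path / "e.rd"
        snapshot_write(metrics.aggregate([]), [], out)
        back, _ = snapshot_read(out)
        assert back.n_reads == 0 and back.total_bases == 0

    def test_provenance_round_trip(self, tmp_path, fastq_path):
        stats = _stats_for(list(formats.read_file(fastq_path)))
        src = SourceInfo.from_file(fastq_path, stats.n_reads)
        out = tmp_path / "s.rd"
        snapshot_write(stats, [src], out)
        _, header = snapshot_read(out)
        assert header.sources == [src]
        assert header.sources[0].md5 == md5_file(fastq_path)

    def test_median_array_round_trip(self, rng, tmp_path):
        records = random_records(rng, 200)
        stats = metrics.aggregate_records(records, keep_median=True)
        out = tmp_path / "m.rd"
        snapshot_write(stats, [], out)
        back, header = snapshot_read(out)
        assert header.has_median
        assert back == quantized(stats)

    def test_byte_deterministic_output(self, hifi_stats, tmp_path):
        a, b = tmp_path / "a.rd", tmp_path / "b.rd"
        snapshot_write(hifi_stats, [], a)
        snapshot_write(hifi_stats, [], b)
        assert a.read_bytes() == b.read_bytes()

    def test_payload_contains_no_sequence_characters(self, tmp_path):
        # reads are all-A homopolymers; a payload leaking sequence would
        # show long runs of 'A' (0x41)
        records = [ReadRecord(f"r{i}", "A" * 400) for i in range(50)]
        out = tmp_path / "s.rd"
        snapshot_write(_stats_for(records), [], out)
        blob = out.read_bytes()
        (payload_size,) = struct.unpack_from("<Q", blob, 11)
        payload = gzip.decompress(blob[19:])
        assert len(payload) == payload_size
        assert b"A" * 10 not in payload
        assert len(out.read_bytes()) < sum(len(r.sequence) for r in records)


class TestCorruption:
    def test_bad_magic(self, tmp_path):
        p = tmp_path / "x.rd"
        p.write_bytes(b"NOPE" + b"\x00" * 40)
        with pytest.raises(NotASnapshotError):
            snapshot_read(p)

    def test_unsupported_version(self, tmp_path, hifi_stats):
        p = tmp_path / "x.rd"
        snapshot_write(hifi_stats, [], p)
        blob = bytearray(p.read_bytes())
        blob[4:6] = struct.pack("<H", 99)
        p.write_bytes(bytes(blob))
        with pytest.raises(SnapshotVersionError):
            snapshot_read(p)

    def test_truncated_payload_is_an_error_not_partial_stats(self, tmp_path, hifi_stats):
        p = tmp_path / "x.rd"
        snapshot_write(hifi_stats, [], p)
        p.write_bytes(p.read_bytes()[:-20])
        with pytest.raises(CorruptSnapshotError):
            snapshot_read(p)

    def test_payload_size_mismatch(self, tmp_path, hifi_stats):
        p = tmp_path / "x.rd"
        snapshot_write(hifi_stats, [], p)
        blob = bytearray(p.read_bytes())
        blob[11:19] = struct.pack("<Q", 1)  # lie about the size
        p.write_bytes(bytes(blob))
        with pytest.raises(CorruptSnapshotError, match="mismatch"):
            snapshot_read(p)


class TestMerge:
    def _write(self, records, path, name):
        stats = _stats_for(records)
        src = SourceInfo(name, 123, bytes(range(16)), stats.n_reads)
        snapshot_write(stats, [src], path)
        return stats

    def test_single_input_identity(self, rng, tmp_path):
        a = tmp_path / "a.rd"
        stats = self._write(random_records(rng, 300), a, "a")
        out = tmp_path / "m.rd"
        snapshot_merge([a], out)
        merged, header = snapshot_read(out)
        assert merged == quantized(stats)
        assert [s.path for s in header.sources] == ["a"]

    def test_merge_equals_snapshot_of_concatenation(self, rng, tmp_path):
        recs_a = random_records(rng, 400)
        recs_b = random_records(rng, 250)
        a, b = tmp_path / "a.rd", tmp_path / "b.rd"
        self._write(recs_a, a, "a")
        stats_b = _stats_for(recs_b)
        snapshot_write(stats_b, [SourceInfo("b", 5, b"\x01" * 16, 250)], b)
        out = tmp_path / "m.rd"
        snapshot_merge([a, b], out)
        merged, header = snapshot_read(out)
        direct = _stats_for(recs_a + recs_b)
        assert merged == quantized(direct)
        assert [s.path for s in header.sources] == ["a", "b"]

    def test_merge_commutative_and_associative(self, rng, tmp_path):
        paths = []
        for i in range(3):
            p = tmp_path / f"{i}.rd"
            self._write(random_records(rng, 100 + 50 * i), p, f"src{i}")
            paths.append(p)
        ab_c = tmp_path / "ab_c.rd"
        c_ba = tmp_path / "c_ba.rd"
        ab = tmp_path / "ab.rd"
        ba = tmp_path / "ba.rd"
        snapshot_merge([paths[0], paths[1]], ab)
        snapshot_merge([paths[1], paths[0]], ba)
        s_ab, _ = snapshot_read(ab)
        s_ba, _ = snapshot_read(ba)
        for attr in ("n_reads", "total_bases", "nx_table", "gc_overall", "mean_q"):
            assert getattr(s_ab, attr) == getattr(s_ba, attr)
        assert sorted(s_ab.lengths) == sorted(s_ba.lengths)
        snapshot_merge([ab, paths[2]], ab_c)
        snapshot_merge([paths[2], ba], c_ba)
        s1, _ = snapshot_read(ab_c)
        s2, _ = snapshot_read(c_ba)
        assert s1.nx_table == s2.nx_table
        assert s1.q_histogram.tolist() == s2.q_histogram.tolist()
        assert s1.base_totals.tolist() == s2.base_totals.tolist()

    def test_duplicate_md5_warns_but_merges(self, rng, tmp_path, caplog):
        import logging

        a, b = tmp_path / "a.rd", tmp_path / "b.rd"
        recs = random_records(rng, 50)
        self._write(recs, a, "same")
        self._write(recs, b, "same")
        out = tmp_path / "m.rd"
        with caplog.at_level(logging.WARNING, logger="readqc.snapshot"):
            snapshot_merge([a, b], out)
        assert any("double-count" in m for m in caplog.messages)
        merged, _ = snapshot_read(out)
        assert merged.n_reads == 100

    def test_width_rechosen_for_merged_maximum(self, tmp_path):
        short = _stats_for([ReadRecord("s", "A" * 100)])
        long = _stats_for([ReadRecord("l", "A" * 70_000)])
        a, b = tmp_path / "a.rd", tmp_path / "b.rd"
        snapshot_write(short, [], a)
        snapshot_write(long, [], b)
        out = tmp_path / "m.rd"
        snapshot_merge([a, b], out)
        merged, _ = snapshot_read(out)
        assert merged.lengths.tolist() == [70_000, 100]
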