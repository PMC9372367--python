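"""Event-train data model: readers, segmentation, spike-grid encoding."""

import io

import numpy as np
import pytest

from fetalcoupling.beat_series import (
    BeatSeries,
    SegmentPair,
    SubjectMeta,
    ValidationError,
    encode_segment,
    read_physionet_annotations,
    read_rpeaks_csv,
    segment_minutes,
    write_rpeaks_csv,
    write_segment_manifest,
)
from fetalcoupling.synth import GeneratorConfig, generate_pair


class TestBeatSeries:
    def test_rejects_sub_refractory_rr(self):
        with pytest.raises(ValidationError, match="RR interval"):
            BeatSeries("s1", "maternal", [0.5, 0.6], record_duration=1.0)

    def test_rejects_non_monotonic(self):
        with pytest.raises(ValidationError, match="increasing"):
            BeatSeries("s1", "fetal", [1.0, 0.5], record_duration=2.0)

    def test_rejects_times_outside_record(self):
        with pytest.raises(ValidationError, match="outside"):
            BeatSeries("s1", "maternal", [0.0, 5.0], record_duration=2.0)

    def test_gestational_age_sanity_bound(self):
        with pytest.raises(ValidationError):
            SubjectMeta(gestational_age=50.0)


class TestRpeaksCsv:
    def test_direct_parse(self):
        csv = io.StringIO("subject_id,channel,time_s\ns1,maternal,0.0\ns1,maternal,0.8\ns1,maternal,1.6\n")
        series = read_rpeaks_csv(csv)
        assert len(series) == 1
        assert series[0].channel == "maternal"
        np.testing.assert_allclose(series[0].times, [0.0, 0.8, 1.6])

    def test_header_only_gives_empty_collection(self):
        assert read_rpeaks_csv(io.StringIO("subject_id,channel,time_s\n")) == []

    def test_refractory_violation_names_subject(self):
        csv = io.StringIO("subject_id,channel,time_s\ns9,maternal,0.5\ns9,maternal,0.6\n")
        with pytest.raises(ValidationError, match="s9"):
            read_rpeaks_csv(csv)

    def test_missing_column_is_format_error(self):
        with pytest.raises(ValueError, match="missing column"):
            read_rpeaks_csv(io.StringIO("subject_id,time_s\ns1,0.0\n"))

    def test_duplicates_collapsed_with_warning(self):
        csv = io.StringIO("subject_id,channel,time_s\ns1,fetal,0.0\ns1,fetal,0.0004\ns1,fetal,0.5\n")
        with pytest.warns(UserWarning, match="duplicate"):
            series = read_rpeaks_csv(csv)
        assert len(series[0]) == 2

    def test_round_trip_preserves_times_to_1ms(self, tmp_path):
        maternal, fetal, _ = generate_pair(GeneratorConfig(seed=5))
        path = tmp_path / "rpeaks.csv"
        write_rpeaks_csv([maternal, fetal], path)
        back = {s.channel: s for s in read_rpeaks_csv(path)}
        for orig in (maternal, fetal):
            np.testing.assert_allclose(back[orig.channel].times, orig.times, atol=5.1e-4)


class TestSegmentation:
    def _record(self, duration, seed=0):
        m, f, _ = generate_pair(GeneratorConfig(seed=seed, duration=duration))
        return m, f

    def test_five_minute_record_gives_five_windows(self):
        m, f = self._record(300.0)
        segs = segment_minutes(m, f)
        assert [s.window_start for s in segs] == [0.0, 60.0, 120.0, 180.0, 240.0]
        assert all(s.window_length == 60.0 for s in segs)

    def test_trailing_partial_window_discarded(self):
        m, f = self._record(90.0)
        segs = segment_minutes(m, f)
        assert len(segs) == 1 and segs[0].window_start == 0.0

    def test_short_record_warns_and_returns_empty(self):
        m, f = self._record(45.0)
        with pytest.warns(UserWarning, match="shorter"):
            assert segment_minutes(m, f) == []

    def test_partition_property(self):
        """Every beat inside a usable window appears in exactly one segment."""
        m, f = self._record(300.0, seed=3)
        segs = segment_minutes(m, f)
        for series, attr in ((m, "maternal"), (f, "fetal")):
            pooled = np.concatenate([getattr(s, attr).times for s in segs])
            assert pooled.size == np.unique(pooled).size
            in_windows = series.times[series.times < 300.0]
            np.testing.assert_array_equal(np.sort(pooled), in_windows)

    def test_manifest_columns(self, tmp_path):
        m, f = self._record(120.0)
        df = write_segment_manifest(segment_minutes(m, f), tmp_path / "manifest.csv")
        assert list(df.columns) == ["subject_id", "segment_index", "window_start", "n_maternal", "n_fetal", "usable"]
        assert df["usable"].all()


class TestEncoding:
    def _segment(self, mat, fet, start=0.0):
        return SegmentPair(
            maternal=BeatSeries("s", "maternal", mat, record_duration=start + 60),
            fetal=BeatSeries("s", "fetal", fet, record_duration=start + 60),
            window_start=start,
        )

    def test_round_half_up_rule(self):
        seg = self._segment([0.0005, 1.0, 2.0, 3.0], [0.3, 0.9])
        enc = encode_segment(seg, fs=1000)
        assert enc.grid[0, 1] == 1 and enc.grid[0, 0] == 0  # 0.5 samples -> up

    def test_row_sums_equal_beat_counts(self):
        m, f, _ = generate_pair(GeneratorConfig(seed=2))
        seg = segment_minutes(m, f)[0]
        enc = encode_segment(seg, fs=1000)
        assert enc.grid.shape == (2, 60000)
        assert enc.grid[0].sum() == len(seg.maternal)
        assert enc.grid[1].sum() == len(seg.fetal)

    def test_reduced_rate_grid(self):
        m, f, _ = generate_pair(GeneratorConfig(seed=2))
        seg = segment_minutes(m, f)[0]
        enc = encode_segment(seg, fs=250)
        assert enc.grid.shape == (2, 15000)
        # RR >= 0.2 s is 50 samples at 250 Hz: no collisions
        assert enc.grid[0].sum() == len(seg.maternal)
        assert enc.grid[1].sum() == len(seg.fetal)

    def test_colliding_beats_merge_into_one_sample(self):
        # 0.6 s and 0.9 s both round to sample 1 at fs = 1 Hz
        seg = self._segment([0.0, 1.0, 2.0, 3.0], [0.6, 0.9])
        enc = encode_segment(seg, fs=1)
        assert enc.grid.shape == (2, 60)
        assert enc.grid[1].sum() == 1 and enc.grid[1, 1] == 1
        np.testing.assert_array_equal(enc.grid, encode_segment(seg, fs=1).grid)

    def test_invalid_fs_rejected(self):
        seg = self._segment([0.0, 1.0, 2.0, 3.0], [0.5, 1.5])
        with pytest.raises(ValueError, match="fs"):
            encode_segment(seg, fs=0)


class TestPhysionetReader:
    """The MIT annotation dialect: 2-byte pairs, code in the high 6 bits."""

    @staticmethod
    def _write_record(tmp_path, name, fs, samples, suffix):
        (tmp_path / f"{name}.hea").write_text(f"{name} 1 {fs} {int(fs) * 60}\n")
        data = bytearray()
        prev = 0
        for s in samples:
            delta = s - prev
            assert 0 < delta < 1024
            data += bytes([delta & 0xFF, (1 << 2) | (delta >> 8)])  # NORMAL beat
            prev = s
        data += b"\x00\x00"
        (tmp_path / f"{name}.{suffix}").write_bytes(bytes(data))

    def test_sample_indices_divided_by_fs(self, tmp_path):
        self._write_record(tmp_path, "r01", 1000, [1000, 2000], "fqrs")
        with pytest.warns(UserWarning, match="maternal"):
            out = read_physionet_annotations(tmp_path / "r01")
        np.testing.assert_allclose(out["fetal"].times, [1.0, 2.0])
        assert out["maternal"] is None

    def test_maternal_read_when_present(self, tmp_path):
        self._write_record(tmp_path, "r02", 500, [250, 500, 750], "fqrs")
        self._write_record(tmp_path, "r02", 500, [400, 800], "mqrs")
        out = read_physionet_annotations(tmp_path / "r02")
        np.testing.assert_allclose(out["fetal"].times, [0.5, 1.0, 1.5])
        np.testing.assert_allclose(out["maternal"].times, [0.8, 1.6])

    def test_missing_annotation_file_raises(self, tmp_path):
        (tmp_path / "r03.hea").write_text("r03 1 1000 60000\n")
        with pytest.raises(IOError, match="annotation"):
            read_physionet_annotations(tmp_path / "r03")

    def test_corrupt_header_raises(self, tmp_path):
        (tmp_path / "r04.hea").write_text("r04 1 notafrequency 60000\n")
        self._write_record(tmp_path, "r05", 1000, [500], "fqrs")
        (tmp_path / "r04.fqrs").write_bytes((tmp_path / "r05.fqrs").read_bytes())
        with pytest.raises(IOError, match="frequency"):
            read_physionet_annotations(tmp_path / "r04")
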