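"""Round-trip and validation behavior of the on-disk sensor formats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daras import sensor_io
from daras.core import ActionSegment, FrameLabelTrack, N_JOINTS, SkeletonSequence
from daras.sensor_io import (
    CACHE_CAPACITY,
    CacheCapacityError,
    ChecksumError,
    DepthRangeError,
    FormatError,
    SchemaError,
)


class TestDepthPng:
    @pytest.mark.parametrize(
        "frame",
        [
            np.zeros((4, 4), dtype=np.uint16),
            np.pad(np.array([[2500]], dtype=np.uint16), 2),
            np.arange(30, dtype=np.uint16).reshape(5, 6) * 2000,
        ],
        ids=["all-zero", "single-pixel-2500mm", "gradient"],
    )
    def test_round_trip_exact(self, frame, tmp_path):
        path = sensor_io.write_depth_png(frame, tmp_path / "f.png")
        back = sensor_io.read_depth_png(path)
        np.testing.assert_array_equal(back, frame)

    def test_out_of_range_value_rejected(self, tmp_path):
        frame = np.full((3, 3), 70000, dtype=np.int64)
        with pytest.raises(DepthRangeError):
            sensor_io.write_depth_png(frame, tmp_path / "f.png")

    def test_non_png_file_rejected(self, tmp_path):
        bad = tmp_path / "notpng.png"
        bad.write_bytes(b"this is not an image")
        with pytest.raises(FormatError):
            sensor_io.read_depth_png(bad)


class TestCacheBlocks:
    def test_full_block_round_trip(self):
        frames = [np.full((6, 8), 1234, dtype=np.uint16)] * CACHE_CAPACITY
        blob = sensor_io.pack_cache(frames)
        back = sensor_io.unpack_cache(blob)
        assert len(back) == CACHE_CAPACITY
        for f in back:
            np.testing.assert_array_equal(f, frames[0])

    def test_single_frame_round_trip(self):
        frame = np.arange(12, dtype=np.uint16).reshape(3, 4)
        back = sensor_io.unpack_cache(sensor_io.pack_cache([frame]))
        assert len(back) == 1
        np.testing.assert_array_equal(back[0], frame)

    def test_capacity_exceeded(self):
        frames = [np.zeros((2, 2), dtype=np.uint16)] * (CACHE_CAPACITY + 1)
        with pytest.raises(CacheCapacityError):
            sensor_io.pack_cache(frames)

    def test_tampered_tail_detected(self):
        blob = bytearray(sensor_io.pack_cache([np.ones((4, 4), dtype=np.uint16)]))
        blob[-1] ^= 0xFF
        with pytest.raises(ChecksumError):
            sensor_io.unpack_cache(bytes(blob))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, CACHE_CAPACITY),
        h=st.integers(1, 8),
        w=st.integers(1, 8),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_round_trip_property(self, n, h, w, seed):
        rng = np.random.default_rng(seed)
        frames = [rng.integers(0, 65536, (h, w)).astype(np.uint16)
                  for _ in range(n)]
        back = sensor_io.unpack_cache(sensor_io.pack_cache(frames))
        assert len(back) == n
        for a, b in zip(frames, back):
            np.testing.assert_array_equal(a, b)

    def test_every_payload_byte_is_protected(self):
        """Flipping any single payload byte trips the checksum."""
        blob = sensor_io.pack_cache(
            [np.arange(16, dtype=np.uint16).reshape(4, 4)])
        header = 20  # magic + three u32 fields
        for i in range(header, len(blob) - 4):
            tampered = bytearray(blob)
            tampered[i] ^= 0x01
            with pytest.raises(ChecksumError):
                sensor_io.unpack_cache(bytes(tampered))


def _make_sequence(body_id, T, t0=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return SkeletonSequence(
        joints=rng.normal(0, 1, (T, N_JOINTS, 3)) + (0, 2.5, 1),
        timestamps=t0 + np.arange(T) / 8.0,
        body_id=body_id,
    )


class TestSkeletonStream:
    def test_single_body_round_trip(self, tmp_path):
        seq = _make_sequence(0, 10)
        path = sensor_io.write_skeleton_stream([seq], tmp_path / "s.jsonl")
        out = sensor_io.read_skeleton_stream(path)
        assert list(out) == [0]
        assert out[0].T == 10
        np.testing.assert_allclose(out[0].joints, seq.joints, atol=1e-6)
        assert np.all(np.diff(out[0].timestamps) > 0)

    def test_two_interleaved_bodies_grouped(self, tmp_path):
        a = _make_sequence(0, 5, seed=1)
        b = _make_sequence(1, 5, seed=2)
        path = sensor_io.write_skeleton_stream([a, b], tmp_path / "s.jsonl")
        out = sensor_io.read_skeleton_stream(path)
        assert sorted(out) == [0, 1]
        assert out[0].T == 5 and out[1].T == 5

    def test_empty_file_gives_empty_result(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert sensor_io.read_skeleton_stream(path) == {}

    def test_wrong_joint_count_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"timestamp": 0.0, "body_id": 0, "joints3d": '
            + str([[0.0, 0.0, 0.0]] * 18)
            + "}\n"
        )
        with pytest.raises(SchemaError):
            sensor_io.read_skeleton_stream(path)


class TestSegments:
    def test_round_trip_sorted(self, tmp_path):
        segs = [
            ActionSegment(20, 30, "walking", 0.5),
            ActionSegment(0, 10, "reaching_forward", 0.9, person_id=2),
        ]
        path = sensor_io.write_segments(segs, tmp_path / "seg.tsv")
        back = sensor_io.read_segments(path)
        assert [s.start for s in back] == [0, 20]
        assert back[0].person_id == 2 and back[1].person_id is None
        assert back[0].label == "reaching_forward"

    def test_overlapping_segments_preserved(self, tmp_path):
        segs = [ActionSegment(0, 10, "walking"), ActionSegment(5, 15, "walking")]
        back = sensor_io.read_segments(
            sensor_io.write_segments(segs, tmp_path / "seg.tsv"))
        assert len(back) == 2

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            ActionSegment(5, 5, "walking")


class TestTracks:
    def test_track_round_trip(self, tmp_path, taxonomy):
        track = FrameLabelTrack(
            ["walking"] * 3 + ["none_of_the_above"] * 2, taxonomy)
        back = sensor_io.read_track(
            sensor_io.write_track(track, tmp_path / "t.tsv"))
        assert back.labels == track.labels
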