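"""Annotation cleaning, multi-person filtering, and balancing rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daras.annotation import (
    Clip,
    augment_clip,
    balance_dataset,
    clean_track,
    filter_multiperson,
    mirror_clip,
    resample_clip,
    segments_from_track,
    track_from_segments,
)
from daras.core import ActionSegment, DepthSequence, FrameLabelTrack, N_JOINTS, SkeletonSequence
from daras.synth import inject_second_person
from daras.taxonomy import DEFAULT_TAXONOMY

BG = DEFAULT_TAXONOMY.background


def track_of(*runs):
    labels = []
    for label, n in runs:
        labels.extend([label] * n)
    return FrameLabelTrack(labels, DEFAULT_TAXONOMY)


class TestCleanTrack:
    def test_short_runs_relabeled_long_runs_survive(self):
        track = track_of(
            (BG, 10), ("walking", 3), (BG, 10), ("walking", 4), (BG, 10),
            ("walking", 5), (BG, 10), ("walking", 10), (BG, 10),
        )
        cleaned, keep = clean_track(track)
        segs = [s for s in segments_from_track(cleaned) if s.label != BG]
        assert [s.length for s in segs] == [5, 10]
        assert len(keep) == len(track)  # relabeling only, nothing dropped

    def test_overlong_background_truncated_to_first_50(self):
        track = track_of(("walking", 8), (BG, 300), ("walking", 8))
        cleaned, keep = clean_track(track)
        segs = segments_from_track(cleaned)
        assert [(s.label, s.length) for s in segs] == [
            ("walking", 8), (BG, 50), ("walking", 8)]
        # the FIRST 50 background frames are the ones kept
        np.testing.assert_array_equal(keep[8:58], np.arange(8, 58))

    def test_boundary_150_background_untouched(self):
        track = track_of(("walking", 8), (BG, 150), ("walking", 8))
        cleaned, keep = clean_track(track)
        assert len(cleaned) == len(track)
        assert cleaned.labels == track.labels

    def test_relabeled_short_run_can_merge_and_then_truncate(self):
        # 3-frame action inside a long background becomes background and the
        # merged run is truncated as one
        track = track_of(("walking", 8), (BG, 100), ("walking", 3), (BG, 100))
        cleaned, _ = clean_track(track)
        segs = segments_from_track(cleaned)
        assert [(s.label, s.length) for s in segs] == [("walking", 8), (BG, 50)]

    def test_idempotent(self):
        track = track_of((BG, 200), ("walking", 4), ("reaching_forward", 30),
                         (BG, 160), ("hand_manipulation", 7))
        once, _ = clean_track(track)
        twice, keep2 = clean_track(once)
        assert twice.labels == once.labels
        assert len(keep2) == len(once)


class TestSegmentsTrackConversion:
    def test_run_length_grouping(self):
        track = track_of(("walking", 2), (BG, 3), ("reaching_forward", 1))
        segs = segments_from_track(track)
        assert [(s.start, s.end, s.label) for s in segs] == [
            (0, 2, "walking"), (2, 5, BG), (5, 6, "reaching_forward")]

    def test_constant_track_single_segment(self):
        segs = segments_from_track(track_of(("walking", 9)))
        assert len(segs) == 1 and segs[0].length == 9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(DEFAULT_TAXONOMY.labels),
                    min_size=1, max_size=60))
    def test_round_trip_and_tiling(self, labels):
        track = FrameLabelTrack(labels, DEFAULT_TAXONOMY)
        segs = segments_from_track(track)
        # tiles [0, T) without gaps or overlaps
        assert segs[0].start == 0 and segs[-1].end == len(labels)
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        back = track_from_segments(segs, len(labels), DEFAULT_TAXONOMY)
        assert back.labels == list(labels)


class TestMultiPersonFilter:
    def test_removes_exactly_the_two_person_frames(self, small_session):
        session = inject_second_person(small_session, (10, 20), seed=0)
        filtered, keep = filter_multiperson(session)
        assert filtered.T == small_session.T - 10
        np.testing.assert_array_equal(
            keep, np.concatenate([np.arange(10), np.arange(20, 50)]))
        # surviving frames keep their order and content
        np.testing.assert_array_equal(
            filtered.depth.frames, small_session.depth.frames[keep])

    def test_single_person_is_identity(self, small_session):
        filtered, keep = filter_multiperson(small_session)
        assert filtered.T == small_session.T
        np.testing.assert_array_equal(keep, np.arange(small_session.T))

    def test_all_frames_two_person_gives_empty(self, small_session):
        session = inject_second_person(small_session, (0, 50), seed=0)
        filtered, keep = filter_multiperson(session)
        assert filtered.T == 0 and len(keep) == 0


def _clip(label, T=12, seed=0):
    rng = np.random.default_rng(seed)
    frames = rng.integers(1000, 4000, (T, 6, 6)).astype(np.uint16)
    joints = rng.normal(0, 0.3, (T, N_JOINTS, 3)) + (0, 2.5, 1)
    ts = np.arange(T) / 8.0
    return Clip(DepthSequence(frames, ts), SkeletonSequence(joints, ts), label)


class TestAugmentAndBalance:
    def test_mirror_is_involution(self):
        clip = _clip("walking")
        back = mirror_clip(mirror_clip(clip))
        np.testing.assert_array_equal(back.depth.frames, clip.depth.frames)
        np.testing.assert_allclose(back.skeleton.joints, clip.skeleton.joints)

    def test_resample_changes_length(self):
        clip = _clip("walking", T=30)
        out = resample_clip(clip, 36)
        assert out.T == 36 and out.label == "walking"

    def test_augmentation_preserves_label(self):
        for seed in range(6):
            out = augment_clip(_clip("reaching_forward"), seed=seed)
            assert out.label == "reaching_forward"
            assert out.augmented

    def test_balance_bounds_ratios(self):
        clips = ([_clip("walking", seed=i) for i in range(100)]
                 + [_clip("reaching_forward", seed=100 + i) for i in range(20)]
                 + [_clip(BG, seed=200 + i) for i in range(400)])
        out = balance_dataset(clips, DEFAULT_TAXONOMY, seed=0)
        counts = {}
        for c in out:
            counts[c.label] = counts.get(c.label, 0) + 1
        assert counts["reaching_forward"] >= 50
        assert counts[BG] <= 100
        action_counts = [v for k, v in counts.items() if k != BG]
        assert max(action_counts) / min(action_counts) <= 2.0
        assert any(c.augmented for c in out)

    def test_balance_seeded_reproducible(self):
        clips = ([_clip("walking", seed=i) for i in range(10)]
                 + [_clip(BG, seed=50 + i) for i in range(30)])
        a = balance_dataset(clips, DEFAULT_TAXONOMY, seed=3)
        b = balance_dataset(clips, DEFAULT_TAXONOMY, seed=3)
        assert [(c.label, c.T, c.augmented) for c in a] == [
            (c.label, c.T, c.augmented) for c in b]
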