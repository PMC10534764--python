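"""Anchor machinery: generation, offset transforms, IoU, NMS, joint loss."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daras.core import ActionSegment
from daras.proposals import (
    RHCN_ANCHOR_SCALES,
    STROKE_ANCHOR_SCALES,
    assign_anchor_targets,
    decode_offsets,
    encode_offsets,
    generate_anchors,
    joint_loss,
    nms,
    smooth_l1,
    temporal_iou,
)


class TestAnchors:
    def test_count_positions_times_scales(self):
        anchors = generate_anchors(4, STROKE_ANCHOR_SCALES, stride=8)
        assert len(anchors) == 4 * 10

    def test_centers_and_lengths(self):
        anchors = generate_anchors(2, [2], stride=8)
        np.testing.assert_allclose(anchors.centers, [4.0, 12.0])
        np.testing.assert_allclose(anchors.lengths, [2.0, 2.0])

    def test_default_scale_sets(self):
        assert STROKE_ANCHOR_SCALES == (2, 4, 5, 6, 8, 9, 10, 12, 14, 16)
        assert RHCN_ANCHOR_SCALES == (50, 100, 200, 400)


class TestOffsets:
    def test_identity_anchor(self):
        tx, tw = encode_offsets(10.0, 4.0, 10.0, 4.0)
        assert tx == 0.0 and tw == 0.0

    def test_worked_example(self):
        tx, tw = encode_offsets(10.0, 8.0, 8.0, 4.0)
        assert tx == pytest.approx(0.5)
        assert tw == pytest.approx(math.log(2.0))

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            encode_offsets(5.0, 0.0, 5.0, 4.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x=st.floats(-100, 1000),
        w=st.floats(0.1, 500),
        xa=st.floats(-100, 1000),
        wa=st.floats(0.1, 500),
    )
    def test_encode_decode_round_trip(self, x, w, xa, wa):
        tx, tw = encode_offsets(x, w, xa, wa)
        x2, w2 = decode_offsets(tx, tw, xa, wa)
        assert abs(x2 - x) < 1e-9 * max(1.0, abs(x))
        assert abs(w2 - w) < 1e-9 * max(1.0, abs(w))

    def test_bulk_round_trip_1e4(self, rng):
        n = 10_000
        x = rng.uniform(-50, 500, n)
        w = rng.uniform(0.5, 300, n)
        xa = rng.uniform(-50, 500, n)
        wa = rng.uniform(0.5, 300, n)
        tx, tw = encode_offsets(x, w, xa, wa)
        x2, w2 = decode_offsets(tx, tw, xa, wa)
        np.testing.assert_allclose(x2, x, atol=1e-9, rtol=1e-9)
        np.testing.assert_allclose(w2, w, atol=1e-9, rtol=1e-9)


class TestIoU:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 10), (0, 10), 1.0),
            ((0, 10), (20, 30), 0.0),
            ((0, 10), (5, 15), 5 / 15),
        ],
    )
    def test_examples(self, a, b, expected):
        assert temporal_iou(a, b) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s1=st.integers(0, 50), l1=st.integers(1, 50),
        s2=st.integers(0, 50), l2=st.integers(1, 50),
    )
    def test_symmetric_and_one_iff_equal(self, s1, l1, s2, l2):
        a, b = (s1, s1 + l1), (s2, s2 + l2)
        assert temporal_iou(a, b) == pytest.approx(temporal_iou(b, a))
        if a == b:
            assert temporal_iou(a, b) == 1.0
        else:
            assert temporal_iou(a, b) < 1.0


class TestTargetAssignment:
    def test_exact_anchor_is_positive_with_zero_target(self):
        anchors = generate_anchors(3, [8], stride=8)
        gt = [ActionSegment(8, 16, "walking")]  # equals anchor at position 1
        labels, targets, matched = assign_anchor_targets(anchors, gt, 0.7, 0.3)
        assert labels[1] == 1
        np.testing.assert_allclose(targets[1], [0.0, 0.0], atol=1e-12)
        assert matched[1] == 0

    def test_disjoint_anchor_is_negative(self):
        anchors = generate_anchors(1, [4], stride=8)  # anchor [2, 6)
        gt = [ActionSegment(20, 30, "walking")]
        labels, _, _ = assign_anchor_targets(anchors, gt, 0.7, 0.3)
        assert labels[0] == 0

    def test_intermediate_iou_ignored(self):
        # anchor [2, 6); gt chosen for IoU exactly 0.5: intersection 4/union 8
        anchors = generate_anchors(1, [4], stride=8)
        gt = [ActionSegment(2, 10, "walking")]
        labels, _, _ = assign_anchor_targets(anchors, gt, 0.7, 0.3)
        assert labels[0] == -1

    def test_force_best_match_promotes(self):
        anchors = generate_anchors(1, [4], stride=8)
        gt = [ActionSegment(2, 10, "walking")]
        labels, _, _ = assign_anchor_targets(anchors, gt, 0.7, 0.3,
                                             force_best_match=True)
        assert labels[0] == 1


class TestNms:
    def test_duplicate_keeps_higher_score(self):
        segs = [ActionSegment(0, 10, "w", 0.9), ActionSegment(0, 10, "w", 0.8)]
        kept = nms(segs, 0.7)
        assert len(kept) == 1 and kept[0].score == 0.9

    def test_disjoint_all_kept(self):
        segs = [ActionSegment(i * 20, i * 20 + 10, "w", 0.5 + i * 0.1)
                for i in range(3)]
        assert len(nms(segs, 0.3)) == 3

    def test_chain_example(self):
        segs = [
            ActionSegment(0, 10, "w", 0.9),
            ActionSegment(5, 15, "w", 0.8),
            ActionSegment(12, 22, "w", 0.7),
        ]
        kept = nms(segs, 0.3)
        assert [(s.start, s.end) for s in kept] == [(0, 10), (12, 22)]

    def test_order_invariance(self, rng):
        segs = [ActionSegment(int(s), int(s) + int(l), "w", float(sc))
                for s, l, sc in zip(rng.integers(0, 80, 30),
                                    rng.integers(1, 30, 30),
                                    rng.uniform(0, 1, 30))]
        ref = [(s.start, s.end, s.score) for s in nms(segs, 0.4)]
        for seed in range(3):
            shuffled = list(segs)
            np.random.default_rng(seed).shuffle(shuffled)
            out = [(s.start, s.end, s.score) for s in nms(shuffled, 0.4)]
            assert out == ref

    def test_scores_unchanged(self):
        segs = [ActionSegment(0, 10, "w", 0.63)]
        assert nms(segs, 0.5)[0].score == 0.63


class TestJointLoss:
    def test_zero_at_perfect_prediction(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        targets = np.array([0, 1])
        reg = np.array([[0.2, -0.1], [0.0, 0.0]])
        pos = np.array([True, False])
        loss = joint_loss(probs, targets, reg, reg.copy(), pos)
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_regression_inactive_without_positives(self):
        probs = np.full((4, 2), 0.5)
        targets = np.zeros(4, dtype=int)
        reg_pred = np.full((4, 2), 100.0)  # wildly wrong, but all negatives
        base = joint_loss(probs, targets, np.zeros((4, 2)), np.zeros((4, 2)),
                          np.zeros(4, dtype=bool))
        loss = joint_loss(probs, targets, reg_pred, np.zeros((4, 2)),
                          np.zeros(4, dtype=bool))
        assert loss == pytest.approx(base)

    def test_single_positive_regression_term(self):
        probs = np.array([[1.0, 0.0]])
        targets = np.array([0])
        reg_pred = np.array([[0.5, 0.0]])
        reg_tgt = np.zeros((1, 2))
        loss = joint_loss(probs, targets, reg_pred, reg_tgt,
                          np.array([True]), lam=1.0, n_reg=1)
        assert loss == pytest.approx(0.5 * 0.5**2)

    def test_smooth_l1_kink(self):
        np.testing.assert_allclose(
            smooth_l1(np.array([0.5, 1.0, 2.0])), [0.125, 0.5, 1.5])

    def test_nonnegative(self, rng):
        for _ in range(20):
            logits = rng.normal(size=(6, 3))
            probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
            targets = rng.integers(0, 3, 6)
            reg_p = rng.normal(size=(6, 2))
            reg_t = rng.normal(size=(6, 2))
            pos = rng.random(6) < 0.5
            assert joint_loss(probs, targets, reg_p, reg_t, pos) >= 0.0
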