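"""HON4D descriptor: worked examples, projector geometry, oracle equivalence."""

import itertools
import math

import numpy as np
import pytest

from daras.core import DepthSequence
from daras.hon4d import (
    GridError,
    InsufficientFramesError,
    N_PROJECTORS,
    accumulate_histogram,
    build_projectors,
    compute_normals,
    fit_clip_classifier,
    hon4d_descriptor,
)


def naive_normals(frames):
    """Independent triple-loop re-implementation of the normal computation."""
    frames = np.asarray(frames, dtype=float)
    T, H, W = frames.shape
    out = []
    for k in range(T - 1):
        img1, img2 = frames[k], frames[k + 1]
        for y in range(1, H - 1):
            for x in range(1, W - 1):
                dx = img1[y, x + 1] - img1[y, x - 1]
                dy = img1[y + 1, x] - img1[y - 1, x]
                dt = img1[y, x] - img2[y, x]
                v = np.array([dx, dy, dt, -1.0])
                out.append((k, y, x, v / np.linalg.norm(v)))
    return out


def naive_descriptor(frames, projectors, cells=(4, 4, 3)):
    """Brute-force cell binning + histogram + two-stage L2 normalization."""
    frames = np.asarray(frames, dtype=float)
    T, H, W = frames.shape
    cx, cy, ct = cells
    wx, wy, wt = math.ceil(W / cx), math.ceil(H / cy), math.ceil((T - 1) / ct)
    hists = np.zeros((cx * cy * ct, len(projectors)))
    for k, y, x, n in naive_normals(frames):
        bx = min(x // wx, cx - 1)
        by = min(y // wy, cy - 1)
        bt = min(k // wt, ct - 1)
        cell = (bx * cy + by) * ct + bt
        for j, p in enumerate(projectors):
            hists[cell, j] += max(0.0, float(p @ n))
    for c in range(hists.shape[0]):
        norm = np.linalg.norm(hists[c])
        if norm > 0:
            hists[c] /= norm
    vec = hists.ravel()
    return vec / np.linalg.norm(vec)


class TestNormals:
    def test_flat_field_gives_canonical_normal(self):
        frames = np.full((3, 4, 4), 1000.0)
        normals, _ = compute_normals(frames)
        np.testing.assert_allclose(normals, [[0, 0, 0, -1.0]] * len(normals))

    def test_hand_derived_center_pixel(self):
        """3x3 ramp pair: center raw normal is (2, 6, -1, -1)."""
        img1 = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
        img2 = img1 + 1
        normals, coords = compute_normals(np.stack([img1, img2]))
        assert normals.shape == (1, 4)
        raw = normals[0] * np.linalg.norm([2.0, 6.0, -1.0, -1.0])
        np.testing.assert_allclose(raw, [2.0, 6.0, -1.0, -1.0], atol=1e-12)
        np.testing.assert_array_equal(coords[0], [0, 1, 1])

    def test_normal_count_formula(self, rng):
        K, H, W = 5, 6, 7
        frames = rng.integers(0, 3000, (K, H, W))
        normals, _ = compute_normals(frames)
        assert len(normals) == (K - 1) * (H - 2) * (W - 2)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InsufficientFramesError):
            compute_normals(np.zeros((1, 5, 5)))


class TestProjectors:
    def test_exactly_120_unit_vectors(self):
        P = build_projectors()
        assert P.shape == (N_PROJECTORS, 4)
        np.testing.assert_allclose(np.linalg.norm(P, axis=1), 1.0, atol=1e-12)

    def test_closed_under_negation(self):
        P = build_projectors()
        rows = {tuple(np.round(p, 9)) for p in P}
        for p in P:
            assert tuple(np.round(-p, 9)) in rows

    def test_600_cell_vertex_separation(self):
        """Nearest-neighbor dot product in the 600-cell is the golden ratio/2."""
        P = build_projectors()
        dots = P @ P.T
        np.fill_diagonal(dots, -2)
        phi = (1 + math.sqrt(5)) / 2
        assert np.allclose(dots.max(axis=1), phi / 2, atol=1e-9)


class TestHistogram:
    def test_empty_normal_list(self):
        P = build_projectors()
        np.testing.assert_array_equal(
            accumulate_histogram(np.empty((0, 4)), P), np.zeros(len(P)))

    def test_toy_two_projector_example(self):
        proj = np.array([[1, 0, 0, 0], [0, 1, 0, 0.0]])
        normals = np.array([[0.6, 0.8, 0, 0.0]])
        np.testing.assert_allclose(
            accumulate_histogram(normals, proj), [0.6, 0.8])

    def test_projector_aligned_normal(self):
        P = build_projectors()
        hist = accumulate_histogram(P[[17]], P)
        assert hist[17] == pytest.approx(1.0)
        negs = P @ P[17] < 0
        np.testing.assert_array_equal(hist[negs], 0.0)

    def test_order_invariance(self, rng):
        P = build_projectors()
        normals = rng.normal(size=(50, 4))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        a = accumulate_histogram(normals, P)
        b = accumulate_histogram(normals[::-1], P)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestDescriptor:
    def test_default_length_and_unit_norm(self, rng):
        frames = rng.integers(500, 4000, (8, 12, 12))
        d = hon4d_descriptor(frames)
        assert d.values.shape == (4 * 4 * 3 * 120,)
        assert np.linalg.norm(d.values) == pytest.approx(1.0)
        assert d.values.min() >= 0.0

    def test_constant_sequence_identical_cells(self):
        frames = np.full((7, 8, 8), 2222.0)
        d = hon4d_descriptor(frames)
        per_cell = d.values.reshape(48, 120)
        for c in range(1, 48):
            np.testing.assert_allclose(per_cell[c], per_cell[0], atol=1e-12)
        assert np.count_nonzero(per_cell[0]) > 0

    def test_sum_pool_collapses_to_120(self, rng):
        frames = rng.integers(500, 4000, (8, 12, 12))
        d = hon4d_descriptor(frames, pool="sum")
        assert d.values.shape == (120,)

    def test_grid_error_when_too_short(self):
        with pytest.raises(GridError):
            hon4d_descriptor(np.zeros((3, 12, 12)))  # only 2 temporal slices

    @pytest.mark.parametrize("shape", [(4, 6, 6), (4, 8, 8), (5, 7, 8)])
    def test_oracle_equivalence(self, shape, rng):
        """Vectorized descriptor matches the brute-force triple loop."""
        frames = rng.integers(0, 5000, shape).astype(float)
        P = build_projectors()
        fast = hon4d_descriptor(frames, projectors=P).values
        slow = naive_descriptor(frames, P)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_axis_reflection_permutes_bins(self, rng):
        """An orthogonal map that permutes the projector set (here: negating
        the first axis, a symmetry of the 600-cell) permutes histogram bins
        identically."""
        P = build_projectors()
        normals = rng.normal(size=(40, 4))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        reflected = normals * np.array([-1.0, 1.0, 1.0, 1.0])
        key = {tuple(np.round(p, 9)): i for i, p in enumerate(P)}
        perm = np.array([
            key[tuple(np.round(p * np.array([-1.0, 1.0, 1.0, 1.0]), 9))]
            for p in P
        ])
        a = accumulate_histogram(normals, P)
        b = accumulate_histogram(reflected, P)
        np.testing.assert_allclose(b[perm], a, atol=1e-9)


class TestClipClassifier:
    def test_separable_training_data_fit_exactly(self, rng):
        X = np.zeros((40, 10))
        labels = []
        for i in range(40):
            c = i % 4
            X[i, c] = 1.0 + 0.01 * rng.normal()
            labels.append(f"class{c}")
        clf = fit_clip_classifier(list(X), labels, seed=0)
        assert clf.predict_many(list(X)) == labels

    def test_end_to_end_clip_recognition_beats_chance(self, rng):
        """Tiny rendered clips of 5 action classes, HON4D + linear classifier."""
        from daras.synth import NoiseModel, make_skeleton_clip, render_depth, Camera

        camera = Camera(width=20, height=20, focal_px=18.0)
        labels = ["walking", "reaching_overhead", "reaching_forward",
                  "reaching_below_waist", "hand_manipulation"]
        P = build_projectors()
        noise = NoiseModel(depth_sigma_mm=4.0, joint_sigma_m=0.004,
                           dropout_prob=0.0)
        X, y = [], []
        for label in labels:
            for k in range(8):
                seq, _ = make_skeleton_clip(label, 12, noise,
                                            seed=1000 + 31 * k)
                depth = render_depth(seq, camera, noise, seed=7 * k)
                X.append(hon4d_descriptor(depth, projectors=P))
                y.append(label)
        train = [i for i in range(len(y)) if i % 4 != 3]
        test = [i for i in range(len(y)) if i % 4 == 3]
        clf = fit_clip_classifier([X[i] for i in train],
                                  [y[i] for i in train], seed=0)
        preds = clf.predict_many([X[i] for i in test])
        acc = np.mean([p == y[i] for p, i in zip(preds, test)])
        assert acc > 0.2  # chance for 5 balanced classes
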