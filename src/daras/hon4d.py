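"""Histogram of oriented 4D normals (HON4D) over depth sequences.

For each interior pixel of consecutive frame pairs a 4D surface normal
``n = (dz/dx, dz/dy, dz/dt, -1)`` is formed (central spatial differences,
forward temporal difference), unit-normalized, and binned against the 120
vertices of the regular 600-cell: bin k accumulates ``max(0, p_k . n)``.
The sequence volume is partitioned into a 4 x 4 x 3 (width x height x time)
cell grid, per-cell histograms are L2-normalized, concatenated, and the
concatenation is L2-normalized again (5760 values under the defaults).

This is the descriptor half only — no discriminative projector refinement.
A linear max-margin classifier over descriptors recognizes pre-segmented
clips.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import LinearSVC

from .core import DepthSequence

N_PROJECTORS = 120
DEFAULT_CELLS = (4, 4, 3)  # width x height x time


class InsufficientFramesError(ValueError):
    """The sequence is too short for temporal differencing."""


class GridError(ValueError):
    """The sequence cannot support the requested cell grid."""


def compute_normals(depth_seq) -> Tuple[np.ndarray, np.ndarray]:
    """Unit 4D normals for every interior pixel of frames ``0 .. T-2``.

    Returns ``(normals, coords)`` where ``normals`` is (M, 4) and ``coords``
    is (M, 3) integer ``(t, y, x)`` positions. Raw components before
    normalization are ``dx = right - left``, ``dy = down - up``,
    ``dt = current - next``, ``w = -1``; the constant -1 guarantees a nonzero
    vector even on flat regions.
    """
    frames = depth_seq.frames if isinstance(depth_seq, DepthSequence) else np.asarray(depth_seq)
    frames = frames.astype(np.float64)
    T, H, W = frames.shape
    if T < 2:
        raise InsufficientFramesError("need at least 2 frames")
    if H < 3 or W < 3:
        raise GridError("need at least 3 x 3 pixels for central differences")
    cur = frames[:-1]
    nxt = frames[1:]
    dx = cur[:, 1:-1, 2:] - cur[:, 1:-1, :-2]  # right - left
    dy = cur[:, 2:, 1:-1] - cur[:, :-2, 1:-1]  # down - up
    dt = cur[:, 1:-1, 1:-1] - nxt[:, 1:-1, 1:-1]  # current - next
    raw = np.stack(
        [dx.ravel(), dy.ravel(), dt.ravel(), -np.ones(dx.size)], axis=1
    )
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    normals = raw / norms
    tt, yy, xx = np.meshgrid(
        np.arange(T - 1), np.arange(1, H - 1), np.arange(1, W - 1), indexing="ij"
    )
    coords = np.stack([tt.ravel(), yy.ravel(), xx.ravel()], axis=1)
    return normals, coords


def build_projectors() -> np.ndarray:
    """The 120 unit vertices of the regular 600-cell.

    8 permutations of (+-1, 0, 0, 0), 16 sign choices of (+-1/2)^4, and 96
    even permutations of (+-phi, +-1, +-1/phi, 0)/2. The set is closed under
    negation.
    """
    verts = set()
    for i in range(4):
        for s in (1.0, -1.0):
            v = [0.0, 0.0, 0.0, 0.0]
            v[i] = s
            verts.add(tuple(v))
    for signs in itertools.product((0.5, -0.5), repeat=4):
        verts.add(signs)
    phi = (1 + math.sqrt(5)) / 2
    base = (phi / 2, 0.5, 1 / (2 * phi), 0.0)
    even_perms = [p for p in itertools.permutations(range(4)) if _parity(p) == 0]
    for perm in even_perms:
        for signs in itertools.product((1.0, -1.0), repeat=4):
            v = tuple(signs[k] * base[perm[k]] for k in range(4))
            verts.add(tuple(round(c, 12) for c in v))
    out = np.array(sorted(verts))
    assert out.shape == (N_PROJECTORS, 4)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _parity(perm) -> int:
    inv = sum(
        1
        for i in range(len(perm))
        for j in range(i + 1, len(perm))
        if perm[i] > perm[j]
    )
    return inv % 2


def accumulate_histogram(normals: np.ndarray, projectors: np.ndarray) -> np.ndarray:
    """Rectified projector responses summed over normals: one bin per projector."""
    if len(normals) == 0:
        return np.zeros(len(projectors))
    dots = np.asarray(normals) @ np.asarray(projectors).T
    return np.clip(dots, 0.0, None).sum(axis=0)


@dataclass
class Hon4dDescriptor:
    """Concatenated per-cell 120-bin histograms (or cell-summed, see pool)."""

    values: np.ndarray
    grid_shape: Tuple[int, int, int] = DEFAULT_CELLS
    pool: str = "concat"


def _cell_bins(coord: np.ndarray, extent: int, n_cells: int) -> np.ndarray:
    """Partition coordinates in [0, extent) into n_cells ceil-sized bins."""
    width = math.ceil(extent / n_cells)
    return np.minimum(coord // width, n_cells - 1)


def hon4d_descriptor(
    depth_seq,
    cells: Tuple[int, int, int] = DEFAULT_CELLS,
    pool: str = "concat",
    projectors: Optional[np.ndarray] = None,
) -> Hon4dDescriptor:
    """HON4D descriptor of one depth clip over a cell grid.

    ``cells`` counts (width, height, time) cells; ``pool='concat'`` yields
    ``prod(cells) * 120`` values, ``pool='sum'`` collapses cells to 120 bins.
    """
    frames = depth_seq.frames if isinstance(depth_seq, DepthSequence) else np.asarray(depth_seq)
    T, H, W = frames.shape
    cx, cy, ct = cells
    if T - 1 < ct:
        raise GridError(
            f"need at least {ct} temporal slices of normals, have {T - 1}"
        )
    if H < 3 or W < 3:
        raise GridError("need at least 3 x 3 pixels")
    if projectors is None:
        projectors = build_projectors()
    normals, coords = compute_normals(frames)
    bx = _cell_bins(coords[:, 2], W, cx)
    by = _cell_bins(coords[:, 1], H, cy)
    bt = _cell_bins(coords[:, 0], T - 1, ct)
    cell_id = (bx * cy + by) * ct + bt
    n_cells = cx * cy * ct
    resp = np.clip(normals @ projectors.T, 0.0, None)  # (M, 120)
    hists = np.zeros((n_cells, projectors.shape[0]))
    np.add.at(hists, cell_id, resp)
    if pool == "sum":
        vec = hists.sum(axis=0)
    elif pool == "concat":
        norms = np.linalg.norm(hists, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        vec = (hists / norms).ravel()
    else:
        raise ValueError(f"unknown pool mode {pool!r}")
    total = np.linalg.norm(vec)
    if total > 0:
        vec = vec / total
    return Hon4dDescriptor(vec, cells, pool)


class ClipClassifier:
    """Linear max-margin one-vs-rest classifier over HON4D descriptors."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self._svc = LinearSVC(C=C, random_state=seed, max_iter=20000)
        self.classes_ = None

    def fit(self, descriptors: Sequence, labels: Sequence[str]) -> "ClipClassifier":
        X = np.stack([d.values if isinstance(d, Hon4dDescriptor) else d for d in descriptors])
        self._svc.fit(X, np.asarray(labels))
        self.classes_ = self._svc.classes_
        return self

    def predict(self, descriptor) -> str:
        x = descriptor.values if isinstance(descriptor, Hon4dDescriptor) else np.asarray(descriptor)
        return str(self._svc.predict(x[None])[0])

    def predict_many(self, descriptors: Sequence) -> list:
        X = np.stack([d.values if isinstance(d, Hon4dDescriptor) else d for d in descriptors])
        return [str(p) for p in self._svc.predict(X)]


def fit_clip_classifier(descriptors, labels, seed: int = 0) -> ClipClassifier:
    return ClipClassifier(seed=seed).fit(descriptors, labels)
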