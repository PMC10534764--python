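"""Shared temporal-proposal machinery for the anchor-based detectors.

Anchors are intervals parameterized by center ``x_a`` and length ``w_a``,
placed uniformly along the temporal feature map. Predictions regress the
dimensionless offsets ``t_x = (x - x_a) / w_a`` and ``t_w = log(w / w_a)``;
training targets use the same transform against the matched ground truth.
The joint objective is mean softmax cross-entropy plus a smooth-L1 regression
term active only on positive anchors, weighted by a trade-off parameter
``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import ActionSegment

DEFAULT_POS_THR = 0.7
DEFAULT_NEG_THR = 0.3
DEFAULT_PROPOSAL_NMS = 0.7
DEFAULT_DETECTION_NMS = 0.4
DEFAULT_LAMBDA = 1.0

#: anchor scales used for the depth-window detector on the in-home data
STROKE_ANCHOR_SCALES = (2, 4, 5, 6, 8, 9, 10, 12, 14, 16)
#: anchor scales used for the skeleton detector
RHCN_ANCHOR_SCALES = (50, 100, 200, 400)


@dataclass
class AnchorSet:
    """Uniformly spaced anchors: one per (feature position, scale) pair."""

    centers: np.ndarray  # (A,) frame units
    lengths: np.ndarray  # (A,) frame units
    stride: int
    scales: Tuple[int, ...]
    n_positions: int

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def starts(self) -> np.ndarray:
        return self.centers - self.lengths / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.centers + self.lengths / 2.0


def generate_anchors(
    n_positions: int, scales: Sequence[int], stride: int
) -> AnchorSet:
    """Anchors at position j center ``(j + 0.5) * stride``, one per scale."""
    scales = tuple(int(s) for s in scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    centers = np.repeat((np.arange(n_positions) + 0.5) * stride, len(scales))
    lengths = np.tile(np.asarray(scales, dtype=float), n_positions)
    return AnchorSet(centers.astype(float), lengths, stride, scales, n_positions)


def encode_offsets(x, w, x_a, w_a):
    """(center, length) -> (t_x, t_w) relative to an anchor."""
    x, w, x_a, w_a = (np.asarray(v, dtype=float) for v in (x, w, x_a, w_a))
    if np.any(w <= 0) or np.any(w_a <= 0):
        raise ValueError("segment and anchor lengths must be positive")
    return (x - x_a) / w_a, np.log(w / w_a)


def decode_offsets(t_x, t_w, x_a, w_a):
    """Exact inverse of :func:`encode_offsets`."""
    t_x, t_w, x_a, w_a = (np.asarray(v, dtype=float) for v in (t_x, t_w, x_a, w_a))
    return x_a + t_x * w_a, w_a * np.exp(t_w)


def temporal_iou(a: Tuple[float, float], b: Tuple[float, float]) -> float:
    """Intersection over union of two half-open intervals."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(
    starts_a: np.ndarray, ends_a: np.ndarray, starts_b: np.ndarray, ends_b: np.ndarray
) -> np.ndarray:
    """Pairwise temporal IoU: rows index the first set, columns the second."""
    inter = np.clip(
        np.minimum(ends_a[:, None], ends_b[None, :])
        - np.maximum(starts_a[:, None], starts_b[None, :]),
        0.0,
        None,
    )
    union = (ends_a - starts_a)[:, None] + (ends_b - starts_b)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def assign_anchor_targets(
    anchors: AnchorSet,
    gt_segments: Sequence[ActionSegment],
    pos_thr: float = DEFAULT_POS_THR,
    neg_thr: float = DEFAULT_NEG_THR,
    force_best_match: bool = False,
):
    """Label anchors against ground truth and build regression targets.

    Returns ``(labels, targets, matched)`` where ``labels`` is (A,) with 1 for
    positive (best IoU >= pos_thr), 0 for negative (< neg_thr), -1 ignored;
    ``targets`` is (A, 2) offset pairs valid on positives; ``matched`` holds
    the best ground-truth index per anchor. With ``force_best_match`` the
    highest-IoU anchor of every ground-truth segment is promoted to positive
    (useful when no anchor clears the threshold), which loosens the strict
    thresholding rule.
    """
    A = len(anchors)
    labels = np.zeros(A, dtype=int)
    targets = np.zeros((A, 2))
    matched = np.full(A, -1, dtype=int)
    if not gt_segments:
        return labels, targets, matched
    gs = np.array([s.start for s in gt_segments], dtype=float)
    ge = np.array([s.end for s in gt_segments], dtype=float)
    ious = iou_matrix(anchors.starts, anchors.ends, gs, ge)  # (A, G)
    best = ious.argmax(axis=1)
    best_iou = ious[np.arange(A), best]
    labels[:] = -1
    labels[best_iou < neg_thr] = 0
    labels[best_iou >= pos_thr] = 1
    if force_best_match:
        for g in range(len(gt_segments)):
            a = ious[:, g].argmax()
            if ious[a, g] > 0:
                labels[a] = 1
                best[a] = g
    matched[:] = best
    pos = labels == 1
    if pos.any():
        gx = (gs[best[pos]] + ge[best[pos]]) / 2.0
        gw = ge[best[pos]] - gs[best[pos]]
        tx, tw = encode_offsets(gx, gw, anchors.centers[pos], anchors.lengths[pos])
        targets[pos, 0] = tx
        targets[pos, 1] = tw
    return labels, targets, matched


def nms(segments: Sequence[ActionSegment], iou_thr: float) -> List[ActionSegment]:
    """Greedy non-maximum suppression on scored segments.

    Candidates are visited by descending score (ties: earlier start, then
    shorter length); a candidate is kept iff its IoU with every kept segment
    is below the threshold. Scores are passed through unchanged.
    """
    order = sorted(
        segments, key=lambda s: (-s.score, s.start, s.end - s.start)
    )
    kept: List[ActionSegment] = []
    for cand in order:
        if all(
            temporal_iou((cand.start, cand.end), (k.start, k.end)) < iou_thr
            for k in kept
        ):
            kept.append(cand)
    return kept


def smooth_l1(u: np.ndarray) -> np.ndarray:
    """Per-component smooth L1 (Huber with unit kink)."""
    u = np.asarray(u, dtype=float)
    au = np.abs(u)
    return np.where(au < 1.0, 0.5 * u * u, au - 0.5)


def smooth_l1_grad(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.clip(u, -1.0, 1.0)


def joint_loss(
    cls_probs: np.ndarray,
    cls_targets: np.ndarray,
    reg_pred: np.ndarray,
    reg_targets: np.ndarray,
    pos_mask: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    n_reg: Optional[int] = None,
    eps: float = 1e-12,
) -> float:
    """Joint classification + regression objective.

    ``cls_probs`` (N, C) are predicted probabilities, ``cls_targets`` (N,)
    integer classes; ``reg_pred``/``reg_targets`` (N, 2) offset pairs with the
    regression term active only where ``pos_mask`` is set. Zero exactly at
    perfect prediction.
    """
    cls_probs = np.asarray(cls_probs, dtype=float)
    cls_targets = np.asarray(cls_targets, dtype=int)
    n_cls = len(cls_targets)
    ce = 0.0
    if n_cls:
        ce = float(
            -np.log(np.clip(cls_probs[np.arange(n_cls), cls_targets], eps, None)).mean()
        )
    pos_mask = np.asarray(pos_mask, dtype=bool)
    if n_reg is None:
        n_reg = len(pos_mask)
    reg = 0.0
    if n_reg and pos_mask.any():
        diffs = np.asarray(reg_pred, float)[pos_mask] - np.asarray(reg_targets, float)[pos_mask]
        reg = float(smooth_l1(diffs).sum() / n_reg)
    return ce + lam * reg
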