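"""Ensemble vote fusion and evaluation metrics.

Per frame, each of the three detectors casts one label vote. If at least two
agree, the frame takes that label; otherwise it falls back to the background
class. Reported metrics are per-frame precision (fraction of frames whose
predicted label matches ground truth), per-action precision (fraction of
predicted non-background segments matched one-to-one to a same-label ground
truth segment at temporal IoU >= 0.5), and a row-normalized confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ActionSegment, FrameLabelTrack
from .proposals import temporal_iou
from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY


class AlignmentError(ValueError):
    """Tracks to fuse or compare have different lengths."""


def fuse_frame_votes(*tracks: FrameLabelTrack) -> FrameLabelTrack:
    """Majority-of-three fusion: two agreeing votes win, else background.

    Symmetric in its arguments; unanimity (including on background) passes
    through unchanged.
    """
    if len(tracks) != 3:
        raise ValueError("vote fusion expects exactly three tracks")
    T = len(tracks[0])
    if any(len(t) != T for t in tracks):
        raise AlignmentError("tracks must have equal lengths")
    taxonomy = tracks[0].taxonomy
    bg = taxonomy.background
    fused = []
    for f in range(T):
        votes = [t.labels[f] for t in tracks]
        label = bg
        for v in votes:
            if votes.count(v) >= 2:
                label = v
                break
        fused.append(label)
    return FrameLabelTrack(fused, taxonomy)


def per_frame_precision(
    pred: FrameLabelTrack, gt: FrameLabelTrack, exclude_background: bool = False
) -> float:
    """Fraction of frames whose predicted label equals ground truth.

    With ``exclude_background`` only frames whose ground truth is an action
    class are counted.
    """
    if len(pred) != len(gt):
        raise AlignmentError("tracks must have equal lengths")
    if len(gt) == 0:
        return 0.0
    p = np.asarray(pred.labels, dtype=object)
    g = np.asarray(gt.labels, dtype=object)
    if exclude_background:
        mask = g != gt.taxonomy.background
        if not mask.any():
            return 0.0
        p, g = p[mask], g[mask]
    return float((p == g).mean())


def per_action_precision(
    pred_segments: Sequence[ActionSegment],
    gt_segments: Sequence[ActionSegment],
    iou_thr: float = 0.5,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
) -> Tuple[float, bool]:
    """One-to-one greedy matching of predicted action segments to truth.

    Predictions are visited by descending score and matched to the free
    same-label ground-truth segment of highest IoU (>= ``iou_thr``). Returns
    ``(precision, warning)``; the warning flag is set when there are no
    non-background predictions, in which case precision is defined as 0.
    """
    bg = taxonomy.background
    preds = [s for s in pred_segments if s.label != bg]
    gts = [s for s in gt_segments if s.label != bg]
    if not preds:
        return 0.0, True
    used = [False] * len(gts)
    matched = 0
    for p in sorted(preds, key=lambda s: (-s.score, s.start)):
        best, best_iou = -1, iou_thr
        for gi, g in enumerate(gts):
            if used[gi] or g.label != p.label:
                continue
            iou = temporal_iou((p.start, p.end), (g.start, g.end))
            if iou >= best_iou:
                best, best_iou = gi, iou
        if best >= 0:
            used[best] = True
            matched += 1
    return matched / len(preds), False


def confusion_matrix(
    pred: FrameLabelTrack, gt: FrameLabelTrack
) -> Tuple[np.ndarray, np.ndarray]:
    """Frame-level confusion: rows are ground truth, columns predictions.

    Returns raw counts and the row-normalized matrix (all-zero rows stay
    zero).
    """
    if len(pred) != len(gt):
        raise AlignmentError("tracks must have equal lengths")
    taxonomy = gt.taxonomy
    n = taxonomy.n_classes
    counts = np.zeros((n, n), dtype=int)
    for p, g in zip(pred.labels, gt.labels):
        counts[taxonomy.index(g), taxonomy.index(p)] += 1
    sums = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sums > 0, counts / sums, 0.0)
    return counts, norm


def macro_precision(pred: FrameLabelTrack, gt: FrameLabelTrack) -> float:
    """Mean per-class frame precision over classes predicted at least once."""
    counts, _ = confusion_matrix(pred, gt)
    col = counts.sum(axis=0)
    diag = np.diag(counts)
    present = col > 0
    if not present.any():
        return 0.0
    return float((diag[present] / col[present]).mean())


@dataclass
class MetricsReport:
    per_frame_precision: float
    per_action_precision: float
    confusion_counts: np.ndarray
    confusion: np.ndarray
    per_frame_precision_actions_only: float = 0.0
    macro_precision: float = 0.0
    no_predictions_warning: bool = False

    def as_dict(self) -> Dict:
        return {
            "per_frame_precision": self.per_frame_precision,
            "per_action_precision": self.per_action_precision,
            "per_frame_precision_actions_only":
                self.per_frame_precision_actions_only,
            "macro_precision": self.macro_precision,
            "no_predictions_warning": self.no_predictions_warning,
            "confusion": self.confusion.tolist(),
            "confusion_counts": self.confusion_counts.tolist(),
        }


def evaluate(
    pred_track: FrameLabelTrack,
    gt_track: FrameLabelTrack,
    pred_segments: Sequence[ActionSegment],
    gt_segments: Sequence[ActionSegment],
    iou_thr: float = 0.5,
) -> MetricsReport:
    """Full report over one (possibly concatenated) prediction/truth pair."""
    taxonomy = gt_track.taxonomy
    pfp = per_frame_precision(pred_track, gt_track)
    pap, warn = per_action_precision(pred_segments, gt_segments, iou_thr, taxonomy)
    counts, norm = confusion_matrix(pred_track, gt_track)
    return MetricsReport(
        per_frame_precision=pfp,
        per_action_precision=pap,
        confusion_counts=counts,
        confusion=norm,
        per_frame_precision_actions_only=per_frame_precision(
            pred_track, gt_track, exclude_background=True),
        macro_precision=macro_precision(pred_track, gt_track),
        no_predictions_warning=warn,
    )
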