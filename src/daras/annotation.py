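"""Label cleaning, multi-person filtering, and class balancing.

The cleaning rules mirror the annotation protocol used for per-frame ground
truth: non-background runs shorter than 5 frames are too brief to be real
actions and are relabeled background; background runs longer than 150 frames
carry no training signal and are truncated to their first 50 frames (the
dropped frames leave the dataset view, so an index map is returned); frames
where more than one person is visible are excluded entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ActionSegment,
    DepthSequence,
    FrameLabelTrack,
    LR_PAIRS,
    SkeletonSequence,
)
from .synth import Session, bodies_per_frame
from .taxonomy import ActionTaxonomy

MIN_ACTION_LEN = 5  # frames; shorter non-background runs are removed
MAX_BACKGROUND_LEN = 150  # background runs longer than this are truncated
BACKGROUND_KEEP = 50  # ... down to their first 50 frames


# ---------------------------------------------------------------------------
# run-length <-> segment conversion


def segments_from_track(track: FrameLabelTrack) -> List[ActionSegment]:
    """Maximal equal-label runs as segments tiling [0, T) with no gaps."""
    segments: List[ActionSegment] = []
    labels = track.labels
    T = len(labels)
    i = 0
    while i < T:
        j = i
        while j < T and labels[j] == labels[i]:
            j += 1
        segments.append(ActionSegment(i, j, labels[i]))
        i = j
    return segments


def track_from_segments(
    segments: Sequence[ActionSegment], T: int, taxonomy: ActionTaxonomy
) -> FrameLabelTrack:
    """Paint segments onto a background track of length ``T``.

    Overlaps are resolved in favor of the higher-score segment, so the inverse
    of :func:`segments_from_track` is exact whenever segments tile [0, T).
    """
    labels = [taxonomy.background] * T
    claimed = np.full(T, -math.inf)
    for seg in segments:
        lo, hi = max(seg.start, 0), min(seg.end, T)
        for f in range(lo, hi):
            if seg.score > claimed[f]:
                labels[f] = seg.label
                claimed[f] = seg.score
    return FrameLabelTrack(labels, taxonomy)


# ---------------------------------------------------------------------------
# cleaning


def clean_track(
    track: FrameLabelTrack,
    min_action_len: int = MIN_ACTION_LEN,
    max_background_len: int = MAX_BACKGROUND_LEN,
    background_keep: int = BACKGROUND_KEEP,
    apply_min_to_background: bool = False,
) -> Tuple[FrameLabelTrack, np.ndarray]:
    """Apply the short-segment and long-background rules.

    Returns the cleaned track plus the indices (into the input) of surviving
    frames. Short non-background runs are *relabeled* background (stream
    lengths stay aligned); overlong background runs are truncated to their
    first ``background_keep`` frames, which drops frames. Runs of exactly
    ``max_background_len`` frames are left alone (the rule is strict).

    The function is idempotent: cleaning a cleaned track is a no-op.
    """
    bg = track.taxonomy.background
    labels = list(track.labels)

    # pass 1: relabel too-short runs as background
    for seg in segments_from_track(FrameLabelTrack(labels, track.taxonomy)):
        short = seg.length < min_action_len
        if short and (seg.label != bg or apply_min_to_background):
            for f in range(seg.start, seg.end):
                labels[f] = bg

    # pass 2: truncate overlong background runs (on the merged runs)
    keep = []
    for seg in segments_from_track(FrameLabelTrack(labels, track.taxonomy)):
        if seg.label == bg and seg.length > max_background_len:
            keep.extend(range(seg.start, seg.start + background_keep))
        else:
            keep.extend(range(seg.start, seg.end))
    keep = np.array(keep, dtype=int)
    cleaned = FrameLabelTrack(
        [labels[i] for i in keep],
        track.taxonomy,
        None if track.person_id is None else track.person_id[keep],
    )
    return cleaned, keep


def filter_multiperson(session: Session) -> Tuple[Session, np.ndarray]:
    """Drop frames in which two or more bodies coexist.

    Surviving frames are re-packed contiguously in their original order; the
    returned index map gives, for each surviving frame, its source index.
    """
    counts = bodies_per_frame(session)
    keep = np.flatnonzero(counts < 2)
    depth = session.depth.select(keep)
    skeletons = [s.select(keep) for s in session.skeletons]
    skeletons = [s for s in skeletons if s.present.any() or s is skeletons[0]]
    track = session.track.select(keep)
    return Session(depth, skeletons, track), keep


# ---------------------------------------------------------------------------
# clip balancing and augmentation


@dataclass
class Clip:
    """A pre-segmented training clip (one action instance)."""

    depth: DepthSequence
    skeleton: SkeletonSequence
    label: str
    augmented: bool = False

    @property
    def T(self) -> int:
        return self.depth.T


def augment_clip(clip: Clip, seed: int = 0) -> Clip:
    """Label-preserving augmentation: resample, mirror, or jitter.

    One transform is drawn per call: temporal resampling within +/-20%,
    horizontal mirroring (depth columns flipped; skeleton x negated with
    left/right joints swapped), or small additive noise.
    """
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, 3)
    if choice == 0:
        factor = rng.uniform(0.8, 1.2)
        new_T = max(MIN_ACTION_LEN, int(round(clip.T * factor)))
        clip = resample_clip(clip, new_T)
    elif choice == 1:
        clip = mirror_clip(clip)
    else:
        depth = clip.depth.frames.astype(float)
        depth = np.clip(depth + rng.normal(0, 8.0, depth.shape), 0, 65535)
        joints = clip.skeleton.joints + rng.normal(0, 0.004, clip.skeleton.joints.shape)
        clip = Clip(
            DepthSequence(depth.astype(np.uint16), clip.depth.timestamps, clip.depth.fps),
            SkeletonSequence(joints, clip.skeleton.timestamps, clip.skeleton.body_id),
            clip.label,
        )
    return replace(clip, augmented=True)


def resample_clip(clip: Clip, new_T: int) -> Clip:
    """Temporal resampling by nearest-frame (depth) / linear (skeleton)."""
    old_T = clip.T
    pos = np.linspace(0, old_T - 1, new_T)
    near = np.rint(pos).astype(int)
    frames = clip.depth.frames[near]
    ts = np.arange(new_T) / clip.depth.fps
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, old_T - 1)
    w = (pos - lo)[:, None, None]
    joints = (1 - w) * clip.skeleton.joints[lo] + w * clip.skeleton.joints[hi]
    return Clip(
        DepthSequence(frames, ts, clip.depth.fps),
        SkeletonSequence(joints, ts, clip.skeleton.body_id),
        clip.label,
        clip.augmented,
    )


def mirror_clip(clip: Clip) -> Clip:
    """Horizontal mirror; an involution up to the depth column flip."""
    frames = clip.depth.frames[:, :, ::-1].copy()
    joints = clip.skeleton.joints.copy()
    joints[:, :, 0] *= -1.0
    for li, ri in LR_PAIRS:
        joints[:, [li, ri]] = joints[:, [ri, li]]
    return Clip(
        DepthSequence(frames, clip.depth.timestamps, clip.depth.fps),
        SkeletonSequence(joints, clip.skeleton.timestamps, clip.skeleton.body_id),
        clip.label,
        clip.augmented,
    )


def balance_dataset(
    clips: Sequence[Clip],
    taxonomy: ActionTaxonomy,
    max_ratio: float = 2.0,
    seed: int = 0,
) -> List[Clip]:
    """Augment rare action classes and down-sample background.

    After balancing, the max/min per-class clip count ratio among action
    classes is at most ``max_ratio`` and the background count does not exceed
    the largest action-class count. Added clips are marked ``augmented``.
    """
    rng = np.random.default_rng(seed)
    by_label: Dict[str, List[Clip]] = {}
    for c in clips:
        by_label.setdefault(c.label, []).append(c)
    bg = taxonomy.background
    action_counts = {l: len(v) for l, v in by_label.items() if l != bg}
    if not action_counts:
        return list(clips)
    max_count = max(action_counts.values())
    target_min = math.ceil(max_count / max_ratio)

    out: List[Clip] = []
    for label, group in by_label.items():
        if label == bg:
            if len(group) > max_count:
                pick = rng.choice(len(group), size=max_count, replace=False)
                group = [group[i] for i in sorted(pick)]
            out.extend(group)
            continue
        out.extend(group)
        n_extra = target_min - len(group)
        for k in range(max(0, n_extra)):
            src = group[int(rng.integers(0, len(group)))]
            out.append(augment_clip(src, seed=int(rng.integers(0, 2**31 - 1))))
    return out
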