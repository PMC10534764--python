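"""In-memory containers shared across the pipeline.

Conventions frozen here and used everywhere else:

* frames are indexed 0-based; temporal intervals are half-open ``[start, end)``;
* depth values are millimeters, stored as non-negative integers;
* 3D joint coordinates are meters in a right-handed frame with ``x`` lateral,
  ``y`` pointing away from the camera, and ``z`` up;
* 2D joint coordinates are pixels (column, row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY

#: Astra-style 19-joint skeleton template (frozen naming; the sensor reports
#: only the count, not names).
JOINT_NAMES = (
    "head",
    "neck",
    "chest",
    "torso",
    "mid_hip",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
    "l_hand",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "r_hand",
    "l_hip",
    "l_knee",
    "l_foot",
    "r_hip",
    "r_knee",
    "r_foot",
)
N_JOINTS = len(JOINT_NAMES)
JOINT_INDEX = {name: i for i, name in enumerate(JOINT_NAMES)}

#: left/right joint pairs, used by the mirroring augmentation.
LR_PAIRS = tuple(
    (JOINT_INDEX["l_" + p], JOINT_INDEX["r_" + p])
    for p in ("shoulder", "elbow", "wrist", "hand", "hip", "knee", "foot")
)


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


@dataclass
class DepthSequence:
    """A depth clip: ``T`` frames of per-pixel distances in millimeters."""

    frames: np.ndarray  # (T, H, W) non-negative integers, mm
    timestamps: np.ndarray  # (T,) seconds, strictly increasing
    fps: float = 8.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be T x H x W")
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValidationError("timestamps must match frame count")
        if self.frames.size and self.frames.min() < 0:
            raise ValidationError("depth values must be non-negative")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def T(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def select(self, idx) -> "DepthSequence":
        return DepthSequence(self.frames[idx], self.timestamps[idx], self.fps)


@dataclass
class SkeletonSequence:
    """Per-frame 3D joint positions of one tracked body.

    ``present`` marks frames in which the body was actually observed; absent
    frames keep placeholder coordinates and are ignored by person counting.
    """

    joints: np.ndarray  # (T, 19, 3) meters
    timestamps: np.ndarray  # (T,) seconds
    body_id: int = 0
    joints2d: Optional[np.ndarray] = None  # (T, 19, 2) pixels
    floor_plane: Optional[np.ndarray] = None  # (4,) plane coefficients
    present: Optional[np.ndarray] = None  # (T,) bool

    def __post_init__(self):
        self.joints = np.asarray(self.joints, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.joints.ndim != 3 or self.joints.shape[1:] != (N_JOINTS, 3):
            raise ValidationError(f"joints must be T x {N_JOINTS} x 3")
        if self.joints.shape[0] != self.timestamps.shape[0]:
            raise ValidationError("timestamps must match frame count")
        if not 0 <= self.body_id < 5:
            raise ValidationError("body_id must be in [0, 5)")
        if self.present is None:
            self.present = np.ones(self.joints.shape[0], dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
            if self.present.shape[0] != self.joints.shape[0]:
                raise ValidationError("present mask must match frame count")

    @property
    def T(self) -> int:
        return self.joints.shape[0]

    def select(self, idx) -> "SkeletonSequence":
        return SkeletonSequence(
            self.joints[idx],
            self.timestamps[idx],
            self.body_id,
            None if self.joints2d is None else self.joints2d[idx],
            self.floor_plane,
            self.present[idx],
        )


@dataclass
class FrameLabelTrack:
    """Per-frame action labels over the taxonomy."""

    labels: list
    taxonomy: ActionTaxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)
    person_id: Optional[np.ndarray] = None

    def __post_init__(self):
        self.labels = list(self.labels)
        self.taxonomy.validate(self.labels)
        if self.person_id is not None:
            self.person_id = np.asarray(self.person_id)
            if len(self.person_id) != len(self.labels):
                raise ValidationError("person_id must match track length")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def as_indices(self) -> np.ndarray:
        return np.array([self.taxonomy.index(l) for l in self.labels], dtype=int)

    def select(self, idx) -> "FrameLabelTrack":
        idx = np.asarray(idx)
        return FrameLabelTrack(
            [self.labels[i] for i in idx],
            self.taxonomy,
            None if self.person_id is None else self.person_id[idx],
        )


@dataclass
class ActionSegment:
    """A half-open frame interval with a label and confidence score.

    The center/length parameterization used by anchor regression is exposed as
    ``center = (start + end) / 2`` and ``length = end - start``.
    """

    start: int
    end: int
    label: str
    score: float = 1.0
    person_id: Optional[int] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"segment must be non-empty: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def astuple(self):
        return (self.start, self.end, self.label, self.score, self.person_id)


def segments_to_arrays(segments: Sequence[ActionSegment]):
    """Stack segment bounds into (starts, ends) float arrays."""
    starts = np.array([s.start for s in segments], dtype=float)
    ends = np.array([s.end for s in segments], dtype=float)
    return starts, ends
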