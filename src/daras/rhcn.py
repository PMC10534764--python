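"""Region hierarchical co-occurrence network on skeletal joint streams.

Two input streams — the joint positions S (T x N x D, N = 19 joints, D = 3)
and their frame-to-frame motion M_t = S_{t+1} - S_t (last frame zero-padded
to keep the shape) — pass through point-level layers whose kernels have
extent 1 along the joint axis, so each joint is encoded independently. A
transform stage then swaps the joint axis with the feature axis, after which
convolutions mix all joints and learn global co-occurrence patterns. The two
stream feature maps are concatenated and feed the same temporal proposal and
RoI classification subnets used by the depth detector, on a stride-4
temporal feature map with long anchor scales [50, 100, 200, 400].

Because skeletal data are noisier than depth, only walking detections are
kept by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from . import nn
from .annotation import track_from_segments
from .core import ActionSegment, FrameLabelTrack, JOINT_INDEX, SkeletonSequence
from .detector import (
    DESK_DETECTOR_HYPER,
    DetectorHyper,
    PAPER_DETECTOR_HYPER,
    TemporalDetector,
    train_detector,
)
from .proposals import RHCN_ANCHOR_SCALES
from .synth import impute_missing_joints
from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY

TEMPORAL_STRIDE = 4
DEFAULT_RESTRICT: Set[str] = {"walking"}


class InsufficientFramesError(ValueError):
    pass


def skeleton_motion(S: np.ndarray, pad: str = "zero") -> np.ndarray:
    """First temporal differences of joint positions, same shape as S.

    ``M_t = S_{t+1} - S_t`` for t < T-1; the final row is zero-padded (or a
    repeat of the previous difference with ``pad='repeat'``).
    """
    S = np.asarray(S, dtype=float)
    if S.shape[0] < 2:
        raise InsufficientFramesError("need at least 2 frames")
    M = np.zeros_like(S)
    M[:-1] = S[1:] - S[:-1]
    if pad == "repeat":
        M[-1] = M[-2]
    elif pad != "zero":
        raise ValueError("pad must be 'zero' or 'repeat'")
    return M


def root_center(S: np.ndarray) -> np.ndarray:
    """Subtract the mid-hip trajectory from every joint (per frame)."""
    return S - S[:, JOINT_INDEX["mid_hip"], :][:, None, :]


@dataclass(frozen=True)
class RhcnConfig:
    anchor_scales: Tuple[int, ...] = RHCN_ANCHOR_SCALES
    point_width: int = 8
    cooc_width: int = 16
    head_width: int = 32
    roi_out_len: int = 4
    n_classes: int = 6
    center_root: bool = True
    motion_pad: str = "zero"


class _Stream:
    """Point-level layers -> transform -> co-occurrence layers for one input."""

    def __init__(self, config: RhcnConfig, rng, name: str):
        c1 = config.point_width
        c2 = config.cooc_width
        self.point = nn.Sequential(
            nn.Conv3d(3, c1, kernel=(1, 1, 1), pad=0, rng=rng, name=f"{name}.p1"),
            nn.ReLU(),
            nn.Conv3d(c1, c1, kernel=(3, 1, 1), pad=(1, 0, 0), rng=rng,
                      name=f"{name}.p2"),
            nn.ReLU(),
        )
        # transform: (N, C, T, J, 1) -> (N, J, T, C, 1); joints become channels
        self.transform = nn.Permute((0, 3, 2, 1, 4))
        self.cooc = nn.Sequential(
            nn.Conv3d(19, c2, kernel=(3, 3, 1), pad=(1, 1, 0), rng=rng,
                      name=f"{name}.c1"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 1)),
            nn.Conv3d(c2, c2, kernel=(3, 3, 1), pad=(1, 1, 0), rng=rng,
                      name=f"{name}.c2"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 1)),
            nn.SpatialGlobalMax(),
        )

    def params(self):
        return self.point.params() + self.cooc.params()

    def forward(self, x):
        h = self.point.forward(x)
        h = self.transform.forward(h)
        return self.cooc.forward(h)  # (N, c2, T/4)

    def backward(self, g):
        g = self.cooc.backward(g)
        g = self.transform.backward(g)
        return self.point.backward(g)


class RhcnBackbone:
    def __init__(self, config: RhcnConfig, rng):
        self.s_stream = _Stream(config, rng, "s")
        self.m_stream = _Stream(config, rng, "m")
        c = config.cooc_width
        self.fuse = nn.Sequential(
            nn.Conv1d(2 * c, 2 * c, 3, rng=rng, name="fuse"),
            nn.ReLU(),
        )
        self.out_channels = 2 * c

    def params(self):
        return self.s_stream.params() + self.m_stream.params() + self.fuse.params()

    def forward(self, x):
        s, m = x  # each (1, 3, T, 19, 1)
        fs = self.s_stream.forward(s)
        fm = self.m_stream.forward(m)
        self._split = fs.shape[1]
        return self.fuse.forward(np.concatenate([fs, fm], axis=1))

    def backward(self, g):
        g = self.fuse.backward(g)
        gs = self.s_stream.backward(g[:, : self._split])
        gm = self.m_stream.backward(g[:, self._split :])
        return gs, gm


class RhcnModel(TemporalDetector):
    def __init__(self, config: Optional[RhcnConfig] = None, seed: int = 0):
        config = config or RhcnConfig()
        self.config = config
        rng = np.random.default_rng(seed)
        backbone = RhcnBackbone(config, rng)
        super().__init__(
            backbone,
            stride=TEMPORAL_STRIDE,
            scales=config.anchor_scales,
            roi_out_len=config.roi_out_len,
            head_width=config.head_width,
            n_classes=config.n_classes,
            feature_channels=backbone.out_channels,
            seed=seed,
        )


def build_rhcn(config: Optional[RhcnConfig] = None, seed: int = 0) -> RhcnModel:
    return RhcnModel(config, seed=seed)


def prepare_skeleton_input(
    seq: SkeletonSequence | np.ndarray, config: Optional[RhcnConfig] = None
) -> Tuple[Tuple[np.ndarray, np.ndarray], int]:
    """Impute dropouts, build (S, M) stream tensors, pad T to the stride."""
    config = config or RhcnConfig()
    S = seq.joints if isinstance(seq, SkeletonSequence) else np.asarray(seq, float)
    if np.isnan(S).any():
        S = impute_missing_joints(S)
    T = S.shape[0]
    M = skeleton_motion(S, pad=config.motion_pad)
    if config.center_root:
        S = root_center(S)
    pad = (-T) % TEMPORAL_STRIDE
    if pad:
        S = np.concatenate([S, np.repeat(S[-1:], pad, axis=0)])
        M = np.concatenate([M, np.zeros((pad,) + M.shape[1:])])
    def to_tensor(a):
        a = np.moveaxis(a, 2, 0)[None, :, :, :, None]  # (1, 3, T, 19, 1)
        return a.astype(nn.DTYPE)
    return (to_tensor(S), to_tensor(M)), T


def make_rhcn_dataset(skeletons, tracks, config: Optional[RhcnConfig] = None):
    from .annotation import segments_from_track

    data = []
    for seq, track in zip(skeletons, tracks):
        x, T = prepare_skeleton_input(seq, config)
        bg = track.taxonomy.background
        gt = [s for s in segments_from_track(track) if s.label != bg]
        data.append((x, gt, T))
    return data


def train_rhcn(
    model: RhcnModel,
    dataset,
    hyper: Optional[DetectorHyper] = None,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
    seed: int = 0,
    verbose: bool = False,
) -> List[float]:
    return train_detector(model, dataset, hyper or DESK_DETECTOR_HYPER,
                          taxonomy, seed=seed, verbose=verbose)


def detect_rhcn(
    model: RhcnModel,
    skeleton_seq: SkeletonSequence | np.ndarray,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
    restrict_labels: Optional[Set[str]] = frozenset(DEFAULT_RESTRICT),
    **kwargs,
) -> Tuple[List[ActionSegment], FrameLabelTrack]:
    """Detect and paint a track; non-allowed labels are dropped (walking-only
    by default). Pass ``restrict_labels=None`` to keep every class."""
    S = (skeleton_seq.joints if isinstance(skeleton_seq, SkeletonSequence)
         else np.asarray(skeleton_seq, float))
    if S.shape[0] == 0:
        return [], FrameLabelTrack([], taxonomy)
    x, T = prepare_skeleton_input(skeleton_seq, model.config)
    restrict = None if restrict_labels is None else set(restrict_labels)
    segments = model.detect(x, T, taxonomy=taxonomy,
                            restrict_labels=restrict, **kwargs)
    track = track_from_segments(segments, T, taxonomy)
    return segments, track
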