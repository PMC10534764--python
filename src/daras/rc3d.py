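"""R-C3D-style temporal action detector on depth windows.

A shared 3D-conv feature extractor reduces an untrimmed depth sequence to a
temporal feature map at stride 8 (spatial extent max-pooled away); the
proposal subnet scores ten anchor scales per feature position; temporal RoI
pooling and two fully connected stages classify and refine each surviving
proposal. Detections are painted back into a per-frame label track (higher
score wins overlaps) because evaluation and fusion operate per frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .annotation import track_from_segments
from .cdc import normalize_depth
from .core import ActionSegment, DepthSequence, FrameLabelTrack
from .detector import (
    DESK_DETECTOR_HYPER,
    DetectorHyper,
    PAPER_DETECTOR_HYPER,
    TemporalDetector,
    train_detector,
)
from .proposals import STROKE_ANCHOR_SCALES
from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY

TEMPORAL_STRIDE = 8


@dataclass(frozen=True)
class Rc3dConfig:
    in_channels: int = 1
    anchor_scales: Tuple[int, ...] = STROKE_ANCHOR_SCALES
    roi_out_len: int = 4
    widths: Tuple[int, int, int] = (8, 16, 32)
    head_width: int = 64
    n_classes: int = 6

    def __post_init__(self):
        if not self.anchor_scales or list(self.anchor_scales) != sorted(self.anchor_scales):
            raise ValueError("anchor scales must be non-empty ascending")
        if self.roi_out_len < 1:
            raise ValueError("roi_out_len must be >= 1")


class Rc3dBackbone:
    """Three conv/pool stages (temporal stride 8) + spatial global max."""

    def __init__(self, config: Rc3dConfig, rng):
        w = config.widths
        self.net = nn.Sequential(
            nn.Conv3d(config.in_channels, w[0], 3, rng=rng, name="c3d1"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 2)),
            nn.Conv3d(w[0], w[1], 3, rng=rng, name="c3d2"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 2)),
            nn.Conv3d(w[1], w[2], 3, rng=rng, name="c3d3"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 2)),
            nn.SpatialGlobalMax(),
        )
        self.out_channels = w[2]

    def params(self):
        return self.net.params()

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, g):
        return self.net.backward(g)


class Rc3dModel(TemporalDetector):
    def __init__(self, config: Optional[Rc3dConfig] = None, seed: int = 0):
        config = config or Rc3dConfig()
        self.config = config
        rng = np.random.default_rng(seed)
        backbone = Rc3dBackbone(config, rng)
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


def build_rc3d(config: Optional[Rc3dConfig] = None, seed: int = 0) -> Rc3dModel:
    return Rc3dModel(config, seed=seed)


def _prepare_input(depth_seq: DepthSequence) -> Tuple[np.ndarray, int]:
    """Normalize and pad to a multiple of the temporal stride."""
    frames = normalize_depth(depth_seq.frames)
    T = frames.shape[0]
    pad = (-T) % TEMPORAL_STRIDE
    if pad:
        frames = np.concatenate([frames, np.repeat(frames[-1:], pad, axis=0)])
    return frames[None, None], T


def make_rc3d_dataset(sessions, tracks) -> List[Tuple[np.ndarray, list, int]]:
    """(input, gt segments, T) samples from depth sequences + truth tracks."""
    from .annotation import segments_from_track

    data = []
    for depth, track in zip(sessions, tracks):
        x, T = _prepare_input(depth)
        bg = track.taxonomy.background
        gt = [s for s in segments_from_track(track) if s.label != bg]
        data.append((x, gt, T))
    return data


def train_rc3d(
    model: Rc3dModel,
    dataset: Sequence[Tuple[np.ndarray, Sequence[ActionSegment], int]],
    hyper: Optional[DetectorHyper] = None,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
    seed: int = 0,
    verbose: bool = False,
) -> List[float]:
    return train_detector(model, dataset, hyper or DESK_DETECTOR_HYPER,
                          taxonomy, seed=seed, verbose=verbose)


def detect_rc3d(
    model: Rc3dModel,
    depth_seq: DepthSequence,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
    **kwargs,
) -> Tuple[List[ActionSegment], FrameLabelTrack]:
    """Detections (clipped to [0, T)) plus the painted per-frame track."""
    x, T = _prepare_input(depth_seq)
    segments = model.detect(x, T, taxonomy=taxonomy, **kwargs)
    track = track_from_segments(segments, T, taxonomy)
    return segments, track
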