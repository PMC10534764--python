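"""Convolutional–de-convolutional (CDC) per-frame action scorer.

A C3D-style 3D-conv backbone shrinks an L-frame, 112x112 single-channel depth
window to a 4x4 spatial map at L/8 temporal resolution; three de-convolutional
stages (CDC6–CDC8) then collapse space to 1x1 while upsampling time back
through L/4 and L/2 to L, ending in a per-frame softmax over the K+1 classes.
The output for one window is a (K+1, L, 1, 1) score volume; per-frame labels
are the argmax, and action instances follow by grouping equal labels.

The channel widths are scalable so that desk-scale tests train a tiny model;
the 112 -> 4 spatial geometry and the x8 temporal reduction are properties of
the pooling ladder and hold at any width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .annotation import segments_from_track
from .core import DepthSequence, FrameLabelTrack
from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY

DEPTH_FULL_SCALE_MM = 8000.0  # fixed full-scale for normalization
DEPTH_CENTER = 0.5  # subtracted after scaling; zero-centered inputs train far better


class ConfigError(ValueError):
    """A network configuration violates a structural constraint."""


@dataclass(frozen=True)
class CdcConfig:
    input_size: Tuple[int, int] = (112, 112)
    in_channels: int = 1
    window_len: int = 16
    widths: Tuple[int, ...] = (8, 16, 32, 32, 32)  # five backbone stages
    head_width: int = 32
    n_classes: int = 6

    def __post_init__(self):
        if self.window_len % 8 != 0:
            raise ConfigError("window_len must be divisible by 8")
        h, w = self.input_size
        if h % 28 != 0 or w % 28 != 0:
            raise ConfigError("spatial size must be divisible by 28")
        if len(self.widths) != 5:
            raise ConfigError("widths must give five backbone stages")


@dataclass
class CdcHyper:
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 0.005
    lr_decay: float = 0.1
    lr_decay_every: Optional[int] = 5000
    epochs: int = 4
    batch_size: int = 8
    clip_norm: float = None


#: training hyperparameters as used on the in-home recordings
PAPER_CDC_HYPER = CdcHyper()
#: fast profile for small synthetic experiments
DESK_CDC_HYPER = CdcHyper(lr=1e-2, weight_decay=1e-4, lr_decay=0.5,
                          lr_decay_every=900, epochs=16, batch_size=8,
                          clip_norm=5.0)


def _spatial_after_backbone(size: int) -> int:
    for _ in range(5):  # five halvings, ceil mode
        size = -(-size // 2)
    return size


class CdcModel:
    """Backbone + de-convolutional head; see module docstring."""

    def __init__(self, config: CdcConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.widths
        self.backbone = nn.Sequential(
            nn.Conv3d(config.in_channels, w[0], 3, rng=rng, name="conv1"),
            nn.ReLU(),
            nn.MaxPool3d((1, 2, 2)),
            nn.Conv3d(w[0], w[1], 3, rng=rng, name="conv2"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 2)),
            nn.Conv3d(w[1], w[2], 3, rng=rng, name="conv3"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 2)),
            nn.Conv3d(w[2], w[3], 3, rng=rng, name="conv4"),
            nn.ReLU(),
            nn.MaxPool3d((2, 2, 2)),
            nn.Conv3d(w[3], w[4], 3, rng=rng, name="conv5"),
            nn.ReLU(),
            nn.MaxPool3d((1, 2, 2)),
        )
        s = _spatial_after_backbone(config.input_size[0])
        hw = config.head_width
        # CDC6 collapses space to 1x1 and doubles time; CDC7/8 double time again
        self.spatial_collapse = nn.Conv3d(w[4], hw, kernel=(1, s, s), pad=0,
                                          rng=rng, name="cdc6s")
        self.head = nn.Sequential(
            nn.ZeroUpsample1d(), nn.Conv1d(hw, hw, 3, rng=rng, name="cdc6t"),
            nn.ReLU(),
            nn.ZeroUpsample1d(), nn.Conv1d(hw, hw, 3, rng=rng, name="cdc7"),
            nn.ReLU(),
            nn.ZeroUpsample1d(), nn.Conv1d(hw, hw, 3, rng=rng, name="cdc8"),
            nn.ReLU(),
            nn.Conv1d(hw, config.n_classes, 1, pad=0, rng=rng, name="fc"),
        )

    def params(self):
        return (self.backbone.params() + self.spatial_collapse.params()
                + self.head.params())

    def forward_backbone(self, x: np.ndarray) -> np.ndarray:
        """C3D-stage feature volume (N, C, L/8, s, s)."""
        return self.backbone.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-frame class logits (N, K+1, L) for windows (N, 1, L, H, W)."""
        f = self.backbone.forward(x)
        f = self.spatial_collapse.forward(f)  # (N, hw, L/8, 1, 1)
        self._sc_shape = f.shape
        f = f[:, :, :, 0, 0]
        return self.head.forward(f)

    def backward(self, gout: np.ndarray) -> None:
        g = self.head.backward(gout)[:, :, :, None, None]
        g = self.spatial_collapse.backward(g)
        self.backbone.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-frame probabilities (N, K+1, L); columns sum to one."""
        logits = self.forward(x)
        return nn.softmax(logits, axis=1)


def build_cdc(config: Optional[CdcConfig] = None, seed: int = 0) -> CdcModel:
    return CdcModel(config or CdcConfig(), seed=seed)


def normalize_depth(frames: np.ndarray) -> np.ndarray:
    """Millimeters -> dimensionless, fixed 8 m full scale, zero-centered."""
    frames = np.asarray(frames, dtype=nn.DTYPE)
    return frames / nn.DTYPE(DEPTH_FULL_SCALE_MM) - nn.DTYPE(DEPTH_CENTER)


def window_video(depth_seq: DepthSequence, window_len: int = 16):
    """Split a sequence into non-overlapping L-frame windows.

    The last window is padded by repeating the final frame. Returns
    ``(windows, valid)`` with windows (Nw, L, H, W) and a boolean mask marking
    real (non-padded) frames.
    """
    frames = depth_seq.frames
    T = frames.shape[0]
    n_win = -(-T // window_len)
    pad = n_win * window_len - T
    if pad:
        frames = np.concatenate([frames, np.repeat(frames[-1:], pad, axis=0)])
    valid = np.ones(n_win * window_len, dtype=bool)
    if pad:
        valid[T:] = False
    windows = frames.reshape(n_win, window_len, *frames.shape[1:])
    return windows, valid.reshape(n_win, window_len)


def train_cdc(
    model: CdcModel,
    windows: np.ndarray,
    frame_labels: np.ndarray,
    hyper: Optional[CdcHyper] = None,
    seed: int = 0,
    verbose: bool = False,
) -> List[float]:
    """SGD training on (Nw, L, H, W) windows with (Nw, L) integer labels.

    Returns the per-epoch mean loss trace. Fully deterministic given the seed.
    """
    hyper = hyper or PAPER_CDC_HYPER
    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.params(), lr=hyper.lr, momentum=hyper.momentum,
                 weight_decay=hyper.weight_decay, lr_decay=hyper.lr_decay,
                 lr_decay_every=hyper.lr_decay_every,
                 clip_norm=hyper.clip_norm)
    X = normalize_depth(windows)[:, None]  # (N, 1, L, H, W)
    Y = np.asarray(frame_labels, dtype=int)
    n = X.shape[0]
    trace = []
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, hyper.batch_size):
            idx = order[lo:lo + hyper.batch_size]
            xb, yb = X[idx], Y[idx]
            logits = model.forward(xb)  # (B, C, L)
            B, C, L = logits.shape
            flat = np.moveaxis(logits, 1, 2).reshape(B * L, C)
            loss, gflat = nn.softmax_ce(flat, yb.reshape(-1))
            gl = np.moveaxis(gflat.reshape(B, L, C), 2, 1)
            opt.zero_grad()
            model.backward(gl)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if verbose:
            print(f"cdc epoch {epoch}: loss {trace[-1]:.4f}")
    return trace


def predict_frames(
    model: CdcModel,
    depth_seq: DepthSequence,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
    window_len: Optional[int] = None,
):
    """Per-frame labels for a whole sequence plus per-window score matrices.

    Padding frames are dropped so the track length equals the input length.
    """
    L = window_len or model.config.window_len
    windows, valid = window_video(depth_seq, L)
    probs = model.predict_proba(normalize_depth(windows)[:, None])  # (Nw,C,L)
    labels_idx = probs.argmax(axis=1)  # (Nw, L)
    flat = labels_idx.reshape(-1)[valid.reshape(-1)]
    track = FrameLabelTrack([taxonomy.labels[i] for i in flat], taxonomy)
    score_matrices = [probs[i] for i in range(probs.shape[0])]
    segments = segments_from_track(track)
    return track, score_matrices, segments
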