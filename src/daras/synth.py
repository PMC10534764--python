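"""Synthetic single-kitchen depth + skeleton sessions with per-frame truth.

The generator animates a 19-joint articulated figure through the six activity
categories, renders it against a flat background plane as a millimeter depth
map (pinhole camera, bone capsules), and emits aligned per-frame labels.
Every clip starts and ends at the rest standing pose so that concatenated
clips hand off smoothly; reaching clips follow the raise -> hold -> lower
convention (the wrist profile is unimodal).

Motion amplitudes and speeds are generator defaults chosen to look like
ordinary kitchen activity at the logger's 8 fps; they are not estimates for
any clinical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DepthSequence,
    FrameLabelTrack,
    JOINT_INDEX,
    N_JOINTS,
    SkeletonSequence,
)
from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY, TaxonomyError


class GeometryError(ValueError):
    """Raised when a skeleton cannot be rendered from the camera pose."""


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: depth sigma (mm), joint sigma (m), joint dropout prob."""

    depth_sigma_mm: float = 5.0
    joint_sigma_m: float = 0.005
    dropout_prob: float = 0.02

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Camera:
    """Pinhole depth camera on the kitchen wall, side view at chest height.

    The camera sits at the world origin looking along +y; image u grows with
    +x and v grows with -z (image rows run downward).
    """

    width: int = 28
    height: int = 28
    focal_px: float = 24.0
    background_mm: int = 4000
    height_m: float = 1.3  # mount height; world z of the optical axis

    @property
    def cx(self) -> float:
        return (self.width - 1) / 2.0

    @property
    def cy(self) -> float:
        return (self.height - 1) / 2.0


@dataclass(frozen=True)
class SyntheticScript:
    """A session recipe: ordered (label, duration) entries plus conditions."""

    entries: Tuple[Tuple[str, int], ...]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    camera: Camera = field(default_factory=Camera)
    fps: float = 8.0
    taxonomy: ActionTaxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple((str(l), int(d)) for l, d in self.entries))
        for label, dur in self.entries:
            if label not in self.taxonomy:
                raise TaxonomyError(f"unknown label {label!r}")
            if dur < 1:
                raise ValueError("entry durations must be >= 1")

    @property
    def total_frames(self) -> int:
        return sum(d for _, d in self.entries)


# ---------------------------------------------------------------------------
# kinematics

#: bones rendered as capsules: (joint a, joint b, radius in meters)
BONES = (
    ("head", "neck", 0.11),
    ("neck", "chest", 0.09),
    ("chest", "torso", 0.13),
    ("torso", "mid_hip", 0.13),
    ("chest", "l_shoulder", 0.06),
    ("chest", "r_shoulder", 0.06),
    ("l_shoulder", "l_elbow", 0.05),
    ("l_elbow", "l_wrist", 0.045),
    ("l_wrist", "l_hand", 0.045),
    ("r_shoulder", "r_elbow", 0.05),
    ("r_elbow", "r_wrist", 0.045),
    ("r_wrist", "r_hand", 0.045),
    ("mid_hip", "l_hip", 0.08),
    ("mid_hip", "r_hip", 0.08),
    ("l_hip", "l_knee", 0.07),
    ("l_knee", "l_foot", 0.06),
    ("r_hip", "r_knee", 0.07),
    ("r_knee", "r_foot", 0.06),
)


def rest_pose(person_y: float = 2.5) -> np.ndarray:
    """Rest standing pose (19 x 3, meters): arms down, facing +x."""
    J = np.zeros((N_JOINTS, 3))

    def put(name, x, z, y=person_y):
        J[JOINT_INDEX[name]] = (x, y, z)

    put("head", 0.0, 1.70)
    put("neck", 0.0, 1.52)
    put("chest", 0.0, 1.40)
    put("torso", 0.0, 1.15)
    put("mid_hip", 0.0, 0.95)
    for side, sy in (("l", 0.12), ("r", -0.12)):
        put(f"{side}_shoulder", 0.0, 1.45, person_y + sy * 1.6)
        put(f"{side}_elbow", 0.02, 1.18, person_y + sy * 1.8)
        put(f"{side}_wrist", 0.04, 0.92, person_y + sy * 1.8)
        put(f"{side}_hand", 0.05, 0.84, person_y + sy * 1.8)
        put(f"{side}_hip", 0.0, 0.95, person_y + sy)
        put(f"{side}_knee", 0.01, 0.50, person_y + sy)
        put(f"{side}_foot", 0.02, 0.05, person_y + sy)
    return J


def _raise_hold_lower(n: int, hold: float = 0.4) -> np.ndarray:
    """Unimodal activation profile in [0, 1]: raise, hold, lower.

    Starts and ends at 0; cosine-eased ramps around a central hold plateau.
    """
    t = np.linspace(0.0, 1.0, n)
    ramp = (1.0 - hold) / 2.0
    prof = np.ones(n)
    up = t < ramp
    down = t > 1.0 - ramp
    prof[up] = 0.5 * (1 - np.cos(np.pi * t[up] / ramp))
    prof[down] = 0.5 * (1 - np.cos(np.pi * (1 - t[down]) / ramp))
    prof[0] = 0.0
    prof[-1] = 0.0
    return prof


def _arm_reach(J: np.ndarray, side: str, target: np.ndarray, a: float) -> None:
    """Blend one arm from rest toward a wrist target by activation ``a``."""
    sh = J[JOINT_INDEX[f"{side}_shoulder"]]
    for name, frac, drop in ((f"{side}_elbow", 0.5, 0.08),
                             (f"{side}_wrist", 1.0, 0.0),
                             (f"{side}_hand", 1.12, -0.02)):
        rest = J[JOINT_INDEX[name]].copy()
        goal = sh + frac * (target - sh)
        goal[2] -= drop
        J[JOINT_INDEX[name]] = (1 - a) * rest + a * goal


IDLE_SWAY_M = 0.008  # idle micro-motion amplitude; below any action threshold


def _animate(label: str, n: int, person_y: float) -> np.ndarray:
    """Noise-free joint trajectories (n x 19 x 3) for one action clip."""
    base = rest_pose(person_y)
    out = np.repeat(base[None], n, axis=0)
    t = np.arange(n)
    prof = _raise_hold_lower(n)

    if label == "walking":
        # pace out and back along the counter (x), returning to the start
        amp = 0.7
        phase = 2 * np.pi * t / max(n - 1, 1)
        dx = amp * np.sin(phase)
        out[:, :, 0] += dx[:, None]
        # leg swing, antiphase left/right; arm counter-swing
        step = 0.22 * np.sin(2 * np.pi * t / 8.0)
        for j, s in (("l_knee", 1), ("l_foot", 1), ("r_knee", -1), ("r_foot", -1)):
            out[:, JOINT_INDEX[j], 0] += s * step
        for j, s in (("l_wrist", -1), ("l_hand", -1), ("r_wrist", 1), ("r_hand", 1)):
            out[:, JOINT_INDEX[j], 0] += 0.5 * s * step
        out[:, JOINT_INDEX["l_foot"], 2] += np.clip(0.08 * np.sin(2 * np.pi * t / 8.0), 0, None)
        out[:, JOINT_INDEX["r_foot"], 2] += np.clip(-0.08 * np.sin(2 * np.pi * t / 8.0), 0, None)
    elif label == "reaching_overhead":
        sh = base[JOINT_INDEX["r_shoulder"]]
        target = sh + np.array([0.18, 0.0, 0.55])  # well above the head
        for k in range(n):
            _arm_reach(out[k], "r", target, prof[k])
    elif label == "reaching_forward":
        sh = base[JOINT_INDEX["r_shoulder"]]
        target = sh + np.array([0.55, 0.0, 0.02])  # forward = facing direction +x
        for k in range(n):
            _arm_reach(out[k], "r", target, prof[k])
    elif label == "reaching_below_waist":
        sh = base[JOINT_INDEX["r_shoulder"]]
        target = sh + np.array([0.30, 0.0, -0.95])  # down past the waist
        for k in range(n):
            _arm_reach(out[k], "r", target, prof[k])
        # slight trunk lean into the reach
        lean = 0.10 * prof
        for j in ("head", "neck", "chest"):
            out[:, JOINT_INDEX[j], 0] += lean
            out[:, JOINT_INDEX[j], 2] -= 0.4 * lean
    elif label == "hand_manipulation":
        # working at the counter: forearm up, small rhythmic wrist motion
        sh = base[JOINT_INDEX["r_shoulder"]]
        hold = sh + np.array([0.32, 0.0, -0.30])
        osc = 0.10 * np.sin(2 * np.pi * t / 5.0)
        for k in range(n):
            _arm_reach(out[k], "r", hold, prof[k])
        out[:, JOINT_INDEX["r_wrist"], 0] += osc * prof
        out[:, JOINT_INDEX["r_hand"], 0] += osc * prof
        out[:, JOINT_INDEX["r_wrist"], 2] += 0.5 * np.abs(osc) * prof
        out[:, JOINT_INDEX["r_hand"], 2] += 0.5 * np.abs(osc) * prof
    elif label == "none_of_the_above":
        sway = IDLE_SWAY_M * np.sin(2 * np.pi * t / 16.0)
        out[:, :, 0] += sway[:, None]
    else:  # pragma: no cover - guarded by the taxonomy check upstream
        raise TaxonomyError(f"unknown label {label!r}")
    return out


def make_skeleton_clip(
    label: str,
    n_frames: int,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    fps: float = 8.0,
    person_y: float = 2.5,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
    t0: float = 0.0,
    body_id: int = 0,
) -> Tuple[SkeletonSequence, FrameLabelTrack]:
    """Generate one constant-label skeleton clip with per-frame truth."""
    if label not in taxonomy:
        raise TaxonomyError(f"unknown label {label!r}")
    if n_frames < 5:
        raise ValueError("clips need at least 5 frames")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    joints = _animate(label, n_frames, person_y)
    if noise.joint_sigma_m > 0:
        joints = joints + rng.normal(0.0, noise.joint_sigma_m, joints.shape)
    if noise.dropout_prob > 0:
        drop = rng.random((n_frames, N_JOINTS)) < noise.dropout_prob
        joints = joints.copy()
        joints[drop] = np.nan
    ts = t0 + np.arange(n_frames) / fps
    seq = SkeletonSequence(joints, ts, body_id=body_id,
                           floor_plane=np.array([0.0, 0.0, 1.0, 0.0]))
    track = FrameLabelTrack([label] * n_frames, taxonomy)
    return seq, track


def impute_missing_joints(joints: np.ndarray) -> np.ndarray:
    """Fill NaN joint coordinates by per-joint linear interpolation in time."""
    out = joints.copy()
    T = out.shape[0]
    tt = np.arange(T)
    for j in range(out.shape[1]):
        for d in range(out.shape[2]):
            col = out[:, j, d]
            bad = np.isnan(col)
            if bad.any():
                if bad.all():
                    col[:] = 0.0
                else:
                    col[bad] = np.interp(tt[bad], tt[~bad], col[~bad])
    return out


# ---------------------------------------------------------------------------
# rendering


def _project(camera: Camera, pts: np.ndarray) -> np.ndarray:
    """World (x, y, z) -> (u, v, depth_m). y must be positive (in front)."""
    y = pts[..., 1]
    u = camera.focal_px * pts[..., 0] / y + camera.cx
    v = camera.focal_px * (camera.height_m - pts[..., 2]) / y + camera.cy
    return np.stack([u, v, y], axis=-1)


def render_depth(
    skeletons: Sequence[SkeletonSequence] | SkeletonSequence,
    camera: Optional[Camera] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    fps: float = 8.0,
) -> DepthSequence:
    """Render bodies as bone capsules over a constant background plane.

    Each pixel holds the nearest rendered surface distance in millimeters.
    An empty skeleton list produces pure background.
    """
    camera = camera or Camera()
    noise = noise or NoiseModel()
    if isinstance(skeletons, SkeletonSequence):
        skeletons = [skeletons]
    T = skeletons[0].T if skeletons else 0
    for s in skeletons:
        if s.T != T:
            raise ValueError("all bodies must share the frame grid")
    rng = np.random.default_rng(seed)
    H, W = camera.height, camera.width
    uu, vv = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    frames = np.full((max(T, 0), H, W), float(camera.background_mm))

    bone_idx = [(JOINT_INDEX[a], JOINT_INDEX[b], r) for a, b, r in BONES]
    for t in range(T):
        depth = frames[t]
        for seq in skeletons:
            if not seq.present[t]:
                continue
            J = seq.joints[t]
            if np.isnan(J).any():
                J = impute_missing_joints(seq.joints)[t]
            if (J[:, 1] <= 0.05).any():
                raise GeometryError("skeleton behind or at the camera plane")
            P = _project(camera, J)  # (19, 3): u, v, depth_m
            for ia, ib, radius in bone_idx:
                a, b = P[ia], P[ib]
                # 2-D capsule around the projected bone; radius in pixels at
                # the bone's mean depth
                zm = 0.5 * (a[2] + b[2])
                rpx = radius * camera.focal_px / zm
                du, dv = b[0] - a[0], b[1] - a[1]
                L2 = du * du + dv * dv
                if L2 < 1e-12:
                    tpar = np.zeros_like(uu)
                else:
                    tpar = ((uu - a[0]) * du + (vv - a[1]) * dv) / L2
                    tpar = np.clip(tpar, 0.0, 1.0)
                cu = a[0] + tpar * du
                cv = a[1] + tpar * dv
                dist = np.hypot(uu - cu, vv - cv)
                inside = dist <= rpx
                if not inside.any():
                    continue
                zsurf = (a[2] + tpar * (b[2] - a[2])) * 1000.0  # mm
                bulge = radius * 1000.0 * np.sqrt(
                    np.clip(1.0 - (dist / max(rpx, 1e-9)) ** 2, 0.0, 1.0)
                )
                cand = zsurf - bulge
                np.minimum(depth, np.where(inside, cand, np.inf), out=depth)
    if noise.depth_sigma_mm > 0 and T:
        frames = frames + rng.normal(0.0, noise.depth_sigma_mm, frames.shape)
    frames = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    ts = (skeletons[0].timestamps if skeletons and T else np.arange(T) / fps)
    return DepthSequence(frames, ts, fps=fps)


# ---------------------------------------------------------------------------
# sessions


@dataclass
class Session:
    """One synthetic recording: aligned depth, skeleton bodies, and truth."""

    depth: DepthSequence
    skeletons: List[SkeletonSequence]
    track: FrameLabelTrack

    @property
    def T(self) -> int:
        return self.depth.T

    @property
    def primary(self) -> SkeletonSequence:
        return self.skeletons[0]


def make_session(script: SyntheticScript) -> Session:
    """Assemble a full session from a script; pure function of (script, seed).

    Clips are generated per entry (each starting and ending at the rest pose,
    which makes the concatenation hand off smoothly) and rendered jointly.
    """
    rng = np.random.default_rng(script.seed)
    joints_parts, labels = [], []
    t0 = 0.0
    for i, (label, dur) in enumerate(script.entries):
        clip_seed = int(rng.integers(0, 2**31 - 1))
        seq, track = make_skeleton_clip(
            label, dur, noise=script.noise, seed=clip_seed, fps=script.fps,
            taxonomy=script.taxonomy, t0=t0,
        )
        joints_parts.append(seq.joints)
        labels.extend(track.labels)
        t0 += dur / script.fps
    joints = np.concatenate(joints_parts, axis=0)
    T = joints.shape[0]
    ts = np.arange(T) / script.fps
    skeleton = SkeletonSequence(joints, ts, body_id=0,
                                floor_plane=np.array([0.0, 0.0, 1.0, 0.0]))
    depth_seed = int(rng.integers(0, 2**31 - 1))
    depth = render_depth([skeleton], camera=script.camera, noise=script.noise,
                         seed=depth_seed, fps=script.fps)
    return Session(depth, [skeleton], FrameLabelTrack(labels, script.taxonomy))


def inject_second_person(session: Session, span: Tuple[int, int], seed: int = 0) -> Session:
    """Add a second idle body over ``span`` (half-open); labels unchanged."""
    start, end = span
    T = session.T
    start = max(0, start)
    end = min(T, end)
    if end <= start:
        return session
    rng = np.random.default_rng(seed)
    n = end - start
    joints = np.full((T, N_JOINTS, 3), np.nan)
    pose = _animate("none_of_the_above", max(n, 5), person_y=3.2)[:n]
    pose[:, :, 0] += rng.uniform(-0.8, -0.4)  # off to one side
    joints[start:end] = pose
    present = np.zeros(T, dtype=bool)
    present[start:end] = True
    second = SkeletonSequence(
        np.where(np.isnan(joints), 0.0, joints),
        session.primary.timestamps.copy(),
        body_id=1,
        present=present,
    )
    return Session(session.depth, list(session.skeletons) + [second], session.track)


def bodies_per_frame(session: Session) -> np.ndarray:
    """Number of tracked bodies visible in each frame."""
    counts = np.zeros(session.T, dtype=int)
    for seq in session.skeletons:
        counts += seq.present.astype(int)
    return counts
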