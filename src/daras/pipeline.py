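"""End-to-end orchestration: simulate -> prep -> train -> detect -> fuse -> eval.

The desk-scale benchmark trains the three small detectors on synthetic
single-action kitchen sessions (one action instance framed by idle
background) and evaluates the fused per-frame labels on held-out sessions.
All randomness flows from one seed, so a rerun reproduces the same report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import clean_track, segments_from_track
from .cdc import (
    CdcConfig,
    CdcHyper,
    DESK_CDC_HYPER,
    build_cdc,
    predict_frames,
    train_cdc,
    window_video,
)
from .core import DepthSequence, FrameLabelTrack
from .detector import DESK_DETECTOR_HYPER, DetectorHyper, PAPER_DETECTOR_HYPER
from .fusion import MetricsReport, evaluate, fuse_frame_votes
from .rc3d import Rc3dConfig, build_rc3d, detect_rc3d, make_rc3d_dataset, train_rc3d
from .rhcn import RhcnConfig, build_rhcn, detect_rhcn, make_rhcn_dataset, train_rhcn
from .synth import Camera, NoiseModel, Session, SyntheticScript, make_session
from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY

#: desk-scale network configurations (window geometry 28 x 28; tiny widths)
DESK_CDC_CONFIG = CdcConfig(input_size=(28, 28), widths=(4, 8, 8, 8, 8),
                            head_width=16)
DESK_RC3D_CONFIG = Rc3dConfig(widths=(4, 8, 16), head_width=32)
DESK_RHCN_CONFIG = RhcnConfig()
DESK_CAMERA = Camera(width=28, height=28)

#: final-training-loss thresholds above which a run is considered collapsed
#: (stuck at the background prior) and is restarted from a new init
CDC_PLATEAU_LOSS = 0.9
DETECTOR_PLATEAU_LOSS = 1.2


@dataclass
class RunConfig:
    """One self-describing pipeline run."""

    seed: int = 0
    profile: str = "desk"  # 'desk' or 'paper' hyperparameters
    n_train: int = 200
    n_test: int = 50
    lead_frames: Tuple[int, int] = (8, 16)
    action_frames: Tuple[int, int] = (16, 28)
    tail_frames: Tuple[int, int] = (8, 16)
    noise: NoiseModel = field(default_factory=NoiseModel)
    camera: Camera = field(default_factory=lambda: DESK_CAMERA)
    fps: float = 8.0
    min_detection_len: int = 5  # fused runs shorter than this become background
    iou_thr: float = 0.5


def make_single_action_scripts(
    n: int, seed: int, config: RunConfig,
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
) -> List[SyntheticScript]:
    """Scripts with one action instance framed by idle background.

    Action classes cycle so every class is equally represented.
    """
    rng = np.random.default_rng(seed)
    actions = [l for l in taxonomy.labels if l != taxonomy.background]
    scripts = []
    for i in range(n):
        label = actions[i % len(actions)]
        lead = int(rng.integers(*config.lead_frames, endpoint=True))
        dur = int(rng.integers(*config.action_frames, endpoint=True))
        tail = int(rng.integers(*config.tail_frames, endpoint=True))
        entries = (
            (taxonomy.background, lead),
            (label, dur),
            (taxonomy.background, tail),
        )
        scripts.append(SyntheticScript(
            entries=entries, noise=config.noise,
            seed=int(rng.integers(0, 2**31 - 1)),
            camera=config.camera, fps=config.fps, taxonomy=taxonomy,
        ))
    return scripts


def make_cdc_dataset(sessions: Sequence[Session], window_len: int):
    """Stack per-session windows and per-frame integer labels."""
    xs, ys = [], []
    for sess in sessions:
        windows, _ = window_video(sess.depth, window_len)
        idx = sess.track.as_indices()
        pad = windows.shape[0] * window_len - len(idx)
        if pad:
            idx = np.concatenate([idx, np.repeat(idx[-1:], pad)])
        xs.append(windows)
        ys.append(idx.reshape(windows.shape[0], window_len))
    return np.concatenate(xs), np.concatenate(ys)


def suppress_short_runs(track: FrameLabelTrack, min_len: int) -> FrameLabelTrack:
    """Relabel non-background runs shorter than ``min_len`` as background."""
    cleaned, _ = clean_track(track, min_action_len=min_len,
                             max_background_len=10**9)
    return cleaned


@dataclass
class TrainedEnsemble:
    cdc: object
    rc3d: object
    rhcn: object
    taxonomy: ActionTaxonomy

    def predict_session(self, session: Session, min_detection_len: int = 5):
        """Fused track + segments for one session (all three detectors)."""
        t_cdc, _, _ = predict_frames(self.cdc, session.depth, self.taxonomy)
        t_cdc = FrameLabelTrack(t_cdc.labels[: session.T], self.taxonomy)
        _, t_rc3d = detect_rc3d(self.rc3d, session.depth, self.taxonomy)
        _, t_rhcn = detect_rhcn(self.rhcn, session.primary, self.taxonomy)
        fused = fuse_frame_votes(t_cdc, t_rc3d, t_rhcn)
        fused = suppress_short_runs(fused, min_detection_len)
        segments = [s for s in segments_from_track(fused)
                    if s.label != self.taxonomy.background]
        return fused, segments, (t_cdc, t_rc3d, t_rhcn)


def train_ensemble(
    sessions: Sequence[Session],
    seed: int = 0,
    profile: str = "desk",
    taxonomy: ActionTaxonomy = DEFAULT_TAXONOMY,
    cdc_epochs: Optional[int] = None,
    detector_epochs: Optional[int] = None,
    verbose: bool = False,
) -> TrainedEnsemble:
    """Train the three detectors on prepared sessions."""
    if profile == "desk":
        cdc_hyper = DESK_CDC_HYPER
        det_hyper = DESK_DETECTOR_HYPER
    elif profile == "paper":
        from .cdc import PAPER_CDC_HYPER
        cdc_hyper = PAPER_CDC_HYPER
        det_hyper = PAPER_DETECTOR_HYPER
    else:
        raise ValueError("profile must be 'desk' or 'paper'")
    if cdc_epochs is not None:
        cdc_hyper = CdcHyper(**{**asdict(cdc_hyper), "epochs": cdc_epochs})
    if detector_epochs is not None:
        det_hyper = DetectorHyper(**{**asdict(det_hyper),
                                     "epochs": detector_epochs})

    depths = [s.depth for s in sessions]
    tracks = [s.track for s in sessions]
    skeletons = [s.primary for s in sessions]

    # Batch-of-one SGD on tiny models occasionally lands in a plateau where
    # every prediction collapses to background; that state is visible in the
    # final training loss, so a run that ends above the plateau threshold is
    # deterministically retrained from a shifted init seed.
    restarts = 2 if profile == "desk" else 0

    cdc = None
    Xw, Yw = make_cdc_dataset(sessions, DESK_CDC_CONFIG.window_len)
    for attempt in range(restarts + 1):
        cdc = build_cdc(DESK_CDC_CONFIG, seed=seed + 100 * attempt)
        trace = train_cdc(cdc, Xw, Yw, cdc_hyper, seed=seed + 1 + 100 * attempt,
                          verbose=verbose)
        if trace[-1] <= CDC_PLATEAU_LOSS or attempt == restarts:
            break

    rc3d_data = make_rc3d_dataset(depths, tracks)
    rc3d = None
    for attempt in range(restarts + 1):
        rc3d = build_rc3d(DESK_RC3D_CONFIG, seed=seed + 2 + 100 * attempt)
        trace = train_rc3d(rc3d, rc3d_data, det_hyper, taxonomy,
                           seed=seed + 3 + 100 * attempt, verbose=verbose)
        if trace[-1] <= DETECTOR_PLATEAU_LOSS or attempt == restarts:
            break

    rhcn_data = make_rhcn_dataset(skeletons, tracks)
    rhcn = None
    for attempt in range(restarts + 1):
        rhcn = build_rhcn(DESK_RHCN_CONFIG, seed=seed + 4 + 100 * attempt)
        trace = train_rhcn(rhcn, rhcn_data, det_hyper, taxonomy,
                           seed=seed + 5 + 100 * attempt, verbose=verbose)
        if trace[-1] <= DETECTOR_PLATEAU_LOSS or attempt == restarts:
            break
    return TrainedEnsemble(cdc, rc3d, rhcn, taxonomy)


def evaluate_ensemble(
    ensemble: TrainedEnsemble,
    sessions: Sequence[Session],
    min_detection_len: int = 5,
    iou_thr: float = 0.5,
) -> MetricsReport:
    """Pooled metrics over held-out sessions (tracks concatenated)."""
    pred_labels, gt_labels = [], []
    pred_segments, gt_segments = [], []
    offset = 0
    taxonomy = ensemble.taxonomy
    from .core import ActionSegment

    for sess in sessions:
        fused, segs, _ = ensemble.predict_session(sess, min_detection_len)
        pred_labels.extend(fused.labels)
        gt_labels.extend(sess.track.labels)
        for s in segs:
            pred_segments.append(ActionSegment(
                s.start + offset, s.end + offset, s.label, s.score))
        for s in segments_from_track(sess.track):
            if s.label != taxonomy.background:
                gt_segments.append(ActionSegment(
                    s.start + offset, s.end + offset, s.label))
        offset += sess.T
    return evaluate(
        FrameLabelTrack(pred_labels, taxonomy),
        FrameLabelTrack(gt_labels, taxonomy),
        pred_segments, gt_segments, iou_thr,
    )


def run_pipeline(config: RunConfig, outdir: Optional[Path] = None,
                 verbose: bool = False) -> MetricsReport:
    """Full reproducible run; optionally persists a manifest and report."""
    t0 = time.time()
    train_scripts = make_single_action_scripts(
        config.n_train, config.seed, config)
    test_scripts = make_single_action_scripts(
        config.n_test, config.seed + 10_000, config)
    train_sessions = [make_session(s) for s in train_scripts]
    test_sessions = [make_session(s) for s in test_scripts]
    ensemble = train_ensemble(train_sessions, seed=config.seed,
                              profile=config.profile, verbose=verbose)
    report = evaluate_ensemble(ensemble, test_sessions,
                               config.min_detection_len, config.iou_thr)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = report.as_dict()
        payload["elapsed_s"] = time.time() - t0
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))
        manifest = {
            "seed": config.seed,
            "profile": config.profile,
            "n_train": config.n_train,
            "n_test": config.n_test,
            "report_sha256": hashlib.sha256(
                json.dumps(payload, sort_keys=True).encode()).hexdigest(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
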