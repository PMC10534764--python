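"""On-disk formats for the depth logger and its downstream consumers.

Formats
-------
* depth frames: single-channel 16-bit grayscale PNG, pixel value = millimeters;
* ``.dcache`` blocks: the at-rest form of the logger's 30-frame write cache —
  header (magic, frame count, H, W), zlib-compressed raw frames, CRC-32 tail;
* skeleton streams: JSON-lines, one record per body per frame;
* label tracks and segments: TSV.

All writer/reader pairs are exact inverses on valid inputs.
"""

from __future__ import annotations

import json
import struct
import zlib
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .core import (
    ActionSegment,
    DepthSequence,
    FrameLabelTrack,
    N_JOINTS,
    SkeletonSequence,
    ValidationError,
)
from .taxonomy import ActionTaxonomy, DEFAULT_TAXONOMY

MAX_DEPTH_MM = 65535  # 16-bit PNG capacity

CACHE_MAGIC = b"DARASDC\x00"
CACHE_CAPACITY = 30  # frames per write-cache block
_HEADER = struct.Struct("<8sIII")  # magic, count, H, W


class DepthRangeError(ValueError):
    """A depth value does not fit in 16 bits."""


class FormatError(ValueError):
    """A file is not in the expected format."""


class CacheCapacityError(ValueError):
    """A cache block was given more frames than its capacity."""


class ChecksumError(ValueError):
    """A cache block failed tail validation."""


class SchemaError(ValueError):
    """A skeleton record violates the stream schema."""


# ---------------------------------------------------------------------------
# depth PNG


def write_depth_png(frame: np.ndarray, path) -> Path:
    """Write one millimeter depth frame as 16-bit grayscale PNG."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValidationError("depth frame must be 2-D")
    if frame.size and (frame.min() < 0 or frame.max() > MAX_DEPTH_MM):
        raise DepthRangeError(
            f"depth values must lie in [0, {MAX_DEPTH_MM}] mm"
        )
    path = Path(path)
    Image.fromarray(frame.astype(np.uint16)).save(path, format="PNG")
    return path


def read_depth_png(path) -> np.ndarray:
    """Read a 16-bit grayscale PNG back into a millimeter grid."""
    try:
        with Image.open(path) as im:
            if im.format != "PNG":
                raise FormatError(f"{path}: not a PNG file (got {im.format})")
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path}: not an image file") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel depth PNG")
    return arr.astype(np.uint16)


# ---------------------------------------------------------------------------
# cache blocks


def pack_cache(frames: Sequence[np.ndarray]) -> bytes:
    """Pack up to 30 equally-shaped mm frames into one validated block."""
    frames = [np.asarray(f) for f in frames]
    if not 1 <= len(frames) <= CACHE_CAPACITY:
        raise CacheCapacityError(
            f"cache holds 1..{CACHE_CAPACITY} frames, got {len(frames)}"
        )
    shape = frames[0].shape
    if len(shape) != 2 or any(f.shape != shape for f in frames):
        raise ValidationError("all frames must share one H x W shape")
    stack = np.stack(frames)
    if stack.min() < 0 or stack.max() > MAX_DEPTH_MM:
        raise DepthRangeError("depth values must fit in 16 bits")
    raw = stack.astype("<u2").tobytes()
    payload = zlib.compress(raw, level=6)
    header = _HEADER.pack(CACHE_MAGIC, len(frames), shape[0], shape[1])
    tail = struct.pack("<I", zlib.crc32(payload) & 0xFFFFFFFF)
    return header + payload + tail


def unpack_cache(blob: bytes) -> List[np.ndarray]:
    """Inverse of :func:`pack_cache`; validates magic and CRC-32 tail."""
    if len(blob) < _HEADER.size + 4:
        raise FormatError("cache block too short")
    magic, count, h, w = _HEADER.unpack_from(blob, 0)
    if magic != CACHE_MAGIC:
        raise FormatError("bad cache magic")
    payload = blob[_HEADER.size : -4]
    (crc,) = struct.unpack("<I", blob[-4:])
    if zlib.crc32(payload) & 0xFFFFFFFF != crc:
        raise ChecksumError("cache payload failed CRC-32 validation")
    raw = zlib.decompress(payload)
    expected = count * h * w * 2
    if len(raw) != expected:
        raise FormatError("cache payload has wrong size")
    stack = np.frombuffer(raw, dtype="<u2").reshape(count, h, w)
    return [stack[i].copy() for i in range(count)]


def write_cache_file(frames: Sequence[np.ndarray], path) -> Path:
    path = Path(path)
    path.write_bytes(pack_cache(frames))
    return path


def read_cache_file(path) -> List[np.ndarray]:
    return unpack_cache(Path(path).read_bytes())


# ---------------------------------------------------------------------------
# skeleton streams (JSON lines, one record per body per frame)


def write_skeleton_stream(sequences: Sequence[SkeletonSequence], path) -> Path:
    """Serialize per-body sequences as timestamp-ordered JSON-lines records."""
    records = []
    for seq in sequences:
        for t in range(seq.T):
            if not seq.present[t]:
                continue
            rec = {
                "timestamp": float(seq.timestamps[t]),
                "body_id": int(seq.body_id),
                "joints3d": np.round(seq.joints[t], 6).tolist(),
            }
            if seq.joints2d is not None:
                rec["joints2d"] = np.round(seq.joints2d[t], 3).tolist()
            if seq.floor_plane is not None:
                rec["floor_plane"] = np.asarray(seq.floor_plane, float).tolist()
            records.append(rec)
    records.sort(key=lambda r: (r["timestamp"], r["body_id"]))
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return path


def read_skeleton_stream(path) -> Dict[int, SkeletonSequence]:
    """Read a stream and group records into one sequence per body id."""
    per_body: Dict[int, list] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            joints = np.asarray(rec["joints3d"], dtype=float)
            if joints.shape != (N_JOINTS, 3):
                raise SchemaError(
                    f"line {lineno}: record must have exactly {N_JOINTS} joints"
                )
            per_body.setdefault(int(rec["body_id"]), []).append(rec)
    out: Dict[int, SkeletonSequence] = {}
    for body_id, recs in sorted(per_body.items()):
        recs.sort(key=lambda r: r["timestamp"])
        joints = np.array([r["joints3d"] for r in recs], dtype=float)
        ts = np.array([r["timestamp"] for r in recs], dtype=float)
        joints2d = None
        if all("joints2d" in r for r in recs) and recs:
            joints2d = np.array([r["joints2d"] for r in recs], dtype=float)
        floor = recs[0].get("floor_plane") if recs else None
        out[body_id] = SkeletonSequence(
            joints,
            ts,
            body_id=body_id,
            joints2d=joints2d,
            floor_plane=None if floor is None else np.asarray(floor, float),
        )
    return out


# ---------------------------------------------------------------------------
# segments and label tracks (TSV)

_SEG_HEADER = "start\tend\tlabel\tperson_id\tscore"


def write_segments(segments: Sequence[ActionSegment], path) -> Path:
    """Write segments as TSV sorted by start frame (overlaps preserved)."""
    path = Path(path)
    rows = sorted(segments, key=lambda s: (s.start, s.end, s.label))
    with path.open("w") as fh:
        fh.write(_SEG_HEADER + "\n")
        for s in rows:
            pid = "" if s.person_id is None else str(int(s.person_id))
            fh.write(f"{s.start}\t{s.end}\t{s.label}\t{pid}\t{s.score:.6g}\n")
    return path


def read_segments(path) -> List[ActionSegment]:
    segments = []
    with Path(path).open() as fh:
        header = fh.readline()
        if header.strip() != _SEG_HEADER:
            raise FormatError(f"{path}: bad segment file header")
        for line in fh:
            if not line.strip():
                continue
            start, end, label, pid, score = line.rstrip("\n").split("\t")
            segments.append(
                ActionSegment(
                    start=int(start),
                    end=int(end),
                    label=label,
                    score=float(score),
                    person_id=None if pid == "" else int(pid),
                )
            )
    return segments


def write_track(track: FrameLabelTrack, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("frame\tlabel\tperson_id\n")
        for i, lab in enumerate(track.labels):
            pid = ""
            if track.person_id is not None:
                pid = str(int(track.person_id[i]))
            fh.write(f"{i}\t{lab}\t{pid}\n")
    return path


def read_track(path, taxonomy: Optional[ActionTaxonomy] = None) -> FrameLabelTrack:
    taxonomy = taxonomy or DEFAULT_TAXONOMY
    labels, pids = [], []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("frame\tlabel"):
            raise FormatError(f"{path}: bad track file header")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[1])
            pids.append(parts[2] if len(parts) > 2 else "")
    person_id = None
    if any(p != "" for p in pids):
        person_id = np.array([int(p) if p != "" else -1 for p in pids])
    return FrameLabelTrack(labels, taxonomy, person_id)
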