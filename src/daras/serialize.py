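"""Model checkpointing: configs + parameter arrays in a single ``.npz``."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np


def save_model(model, path) -> Path:
    """Persist a CDC / R-C3D / RHCN model (config + weights)."""
    from .cdc import CdcModel
    from .rc3d import Rc3dModel
    from .rhcn import RhcnModel

    kinds = {CdcModel: "cdc", Rc3dModel: "rc3d", RhcnModel: "rhcn"}
    kind = kinds.get(type(model))
    if kind is None:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    payload = {f"param_{i:04d}": p.value for i, p in enumerate(model.params())}
    meta = {"kind": kind, "config": asdict(model.config)}
    path = Path(path)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **payload)
    return path


def load_model(path):
    """Inverse of :func:`save_model`."""
    from .cdc import CdcConfig, CdcModel
    from .rc3d import Rc3dConfig, Rc3dModel
    from .rhcn import RhcnConfig, RhcnModel

    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = meta["config"]
        for key in ("input_size", "widths", "anchor_scales"):
            if key in config and isinstance(config[key], list):
                config[key] = tuple(config[key])
        builders = {
            "cdc": lambda: CdcModel(CdcConfig(**config)),
            "rc3d": lambda: Rc3dModel(Rc3dConfig(**config)),
            "rhcn": lambda: RhcnModel(RhcnConfig(**config)),
        }
        model = builders[meta["kind"]]()
        params = model.params()
        for i, p in enumerate(params):
            stored = data[f"param_{i:04d}"]
            if stored.shape != p.value.shape:
                raise ValueError("checkpoint does not match model layout")
            p.value[...] = stored
    return model
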