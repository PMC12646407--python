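"""Self-describing checkpoints: parameters, batch-norm running statistics
and the architecture configuration in one .npz file."""

from __future__ import annotations

import json

import numpy as np

from .arch import ArchConfig, SVNCNet, build_svnc_net

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(model: SVNCNet, path, extra: dict | None = None) -> None:
    meta = {"arch": model.config.to_dict(), "extra": extra or {}}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[SVNCNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_svnc_net(ArchConfig.from_dict(meta["arch"]))
    model.load_state_dict(state)
    return model, meta.get("extra", {})
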