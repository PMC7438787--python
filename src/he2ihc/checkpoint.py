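"""Single-file model checkpoints: weights + architecture fingerprint."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .nn import NetworkSpec, BlockSpec, ResNet18Classifier, build_classifier

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(net: ResNet18Classifier, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.state_dict()
    np.savez(path, __fingerprint__=np.array(net.spec.fingerprint()), **state)


def load_checkpoint(path: str | Path) -> ResNet18Classifier:
    with np.load(path) as data:
        meta = json.loads(str(data["__fingerprint__"]))
        state = {k: data[k] for k in data.files if k != "__fingerprint__"}
    spec = NetworkSpec(
        input_channels=meta["input_channels"],
        patch_size=meta["patch_size"],
        n_classes=meta["n_classes"],
        stages=tuple(tuple(BlockSpec(k, s) for k, s in stage) for stage in meta["stages"]),
    )
    net = build_classifier(spec, seed=0)
    net.load_state_dict(state)
    return net
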