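"""Checkpoint files: model weights with their config embedded (.npz)."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .coarse_seg import CoarseNetConfig, CoarseUNet
from .prompt_seg import BuiltinPromptNet, PromptSegConfig
from .rejection import RejectionNet, RejectNetConfig

__all__ = ["save_checkpoint", "load_checkpoint"]

_KINDS = {
    CoarseUNet: ("coarse", CoarseNetConfig),
    RejectionNet: ("rejection", RejectNetConfig),
    BuiltinPromptNet: ("prompt", PromptSegConfig),
}
_BUILDERS = {
    "coarse": (CoarseNetConfig, CoarseUNet),
    "rejection": (RejectNetConfig, RejectionNet),
    "prompt": (PromptSegConfig, BuiltinPromptNet),
}


def save_checkpoint(model, path: str) -> None:
    kind, _ = _KINDS[type(model)]
    meta = json.dumps({"kind": kind,
                       "config": dataclasses.asdict(model.config)})
    arrays = {f"p{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path: str):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg_cls, model_cls = _BUILDERS[meta["kind"]]
        cfg_dict = meta["config"]
        for key in ("lesion_count_range", "head_widths", "spacing_mm",
                    "contrast_per_channel"):
            if isinstance(cfg_dict.get(key), list):
                cfg_dict[key] = tuple(cfg_dict[key])
        model = model_cls(cfg_cls(**cfg_dict))
        keys = sorted(k for k in data.files if k.startswith("p"))
        model.load_state_arrays([data[k] for k in keys])
    return model
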