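"""Task settings and model construction.

Four learning-task settings share one encoder-decoder backbone:

* ``STL_lung`` / ``STL_heart`` / ``STL_cord`` — single-task learning, one
  sigmoid segmentation head.
* ``SCOS`` — spatially-correlated organ segmentation: three parallel
  sigmoid heads (lung, heart, spinal cord) on the shared backbone.
* ``TASKS1`` — the three segmentation heads plus a linear distance-map
  regression head.
* ``TASKS2`` — TASKS1 plus three sigmoid contour heads.

Head channels are all 1; every head is a 1x1 convolution on the last
decoder feature map, so the settings differ only in their heads and
losses, never in backbone capacity.
"""

from __future__ import annotations


import json
from dataclasses import dataclass

import numpy as np

from .nn import UNet
from .phantom import ORGANS


@dataclass(frozen=True)
class BackboneConfig:
    depth: int = 3
    base_filters: int = 8
    in_channels: int = 1

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")


@dataclass(frozen=True)
class TaskSetting:
    name: str
    heads: tuple = ()   # (head_name, channels, activation, loss_name)

    @property
    def seg_heads(self):
        return [h[0] for h in self.heads if h[3] == "dice_seg"]

    @property
    def contour_heads(self):
        return [h[0] for h in self.heads if h[3] == "dice_contour"]

    @property
    def has_distance(self):
        return any(h[3] == "sse_distance" for h in self.heads)


def _seg(organ):
    return (organ, 1, "sigmoid", "dice_seg")


def _contour(organ):
    return (f"contour_{organ}", 1, "sigmoid", "dice_contour")


_DIST = ("distance", 1, "linear", "sse_distance")

SETTINGS = {
    "STL_lung": TaskSetting("STL_lung", (_seg("lung"),)),
    "STL_heart": TaskSetting("STL_heart", (_seg("heart"),)),
    "STL_cord": TaskSetting("STL_cord", (_seg("cord"),)),
    "SCOS": TaskSetting("SCOS", tuple(_seg(o) for o in ORGANS)),
    "TASKS1": TaskSetting("TASKS1", tuple(_seg(o) for o in ORGANS) + (_DIST,)),
    "TASKS2": TaskSetting("TASKS2", tuple(_seg(o) for o in ORGANS)
              + tuple(_contour(o) for o in ORGANS) + (_DIST,)),
}


def get_setting(name: str) -> TaskSetting:
    base = name[:-4] if name.endswith("_aug") else name
    if base not in SETTINGS:
        raise KeyError(f"unknown task setting {name!r}")
    return SETTINGS[base]


class SegModel:
    """A backbone + heads for one task setting."""

    def __init__(self, backbone: BackboneConfig, setting: TaskSetting, seed: int = 0):
        self.backbone = backbone
        self.setting = setting
        rng = np.random.default_rng(seed)
        self.net = UNet(backbone.depth, backbone.base_filters,
                        [(n, c, a) for n, c, a, _ in setting.heads], rng,
                        in_channels=backbone.in_channels)

    def predict(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """Forward a batch (N, H, W) or (N, 1, H, W); deterministic."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        return self.net.forward(x)

    def n_params(self) -> int:
        return self.net.n_params()

    # ---- serialization ------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {}
        for i, (_, name, p, _) in enumerate(self.net.parameters()):
            arrays[f"p{i}_{name}"] = p
        meta = json.dumps({"depth": self.backbone.depth,
                           "base_filters": self.backbone.base_filters,
                           "in_channels": self.backbone.in_channels,
                           "setting": self.setting.name})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "SegModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(BackboneConfig(meta["depth"], meta["base_filters"],
                                       meta["in_channels"]),
                        get_setting(meta["setting"]))
            for i, (_, name, p, _) in enumerate(model.net.parameters()):
                p[...] = z[f"p{i}_{name}"]
        return model


def build_model(backbone: BackboneConfig, setting: TaskSetting | str,
                seed: int = 0) -> SegModel:
    if isinstance(setting, str):
        setting = get_setting(setting)
    return SegModel(backbone, setting, seed=seed)
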