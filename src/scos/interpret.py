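"""Saliency and receptive-field analysis for the segmentation models.

Three pixel-attribution maps, all aligned to the input image:

* gradient map — |dS/dI| for S = sum of the head's output probabilities,
  max-normalized for display: which input pixels the task involves.
* guided grad-CAM — elementwise product of a guided-backpropagation
  input gradient (backward pass rectified at every ReLU) and the
  rectified, gradient-weighted channel sum of a chosen layer's
  activations (CAM), bilinearly upsampled to the input size.
* average feature map — channel mean of a layer's activation,
  interpolated to the input size (optionally alpha-blended onto it).

Receptive fields are computed analytically from the layer chain (kernel,
stride, padding), walking the deepest encoder-decoder path; the skip
branches' fields are strict subsets of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .model import BackboneConfig, SegModel


@dataclass
class AttributionMap:
    values: np.ndarray
    kind: str          # guided_gradcam | gradient | avg_feature
    head: str | None
    layer: str | None


@dataclass
class ReceptiveField:
    center: tuple[int, int]
    box: tuple[int, int, int, int]   # (row_min, row_max, col_min, col_max), half-open

    @property
    def height(self) -> int:
        return self.box[1] - self.box[0]

    @property
    def width(self) -> int:
        return self.box[3] - self.box[2]


def _as_batch(image: np.ndarray) -> np.ndarray:
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    return x


def gradient_map(model: SegModel, image: np.ndarray, head: str) -> AttributionMap:
    """|d(sum of head probabilities)/d(input)|, max-normalized."""
    x = _as_batch(image)
    preds = model.net.forward(x)
    if head not in preds:
        raise KeyError(f"model has no head {head!r}")
    d_in = model.net.backward({head: np.ones_like(preds[head])}, accumulate=False)
    g = np.abs(d_in[0, 0]).astype(np.float64)
    peak = g.max()
    if peak > 0:
        g = g / peak
    return AttributionMap(values=g, kind="gradient", head=head, layer=None)


def guided_gradcam(model: SegModel, image: np.ndarray, head: str,
                   cam_layer: str = "last_conv") -> AttributionMap:
    """Guided backprop x upsampled CAM for one head.

    The scalar target is the sum of head probabilities over the predicted
    region (output >= 0.5); if the prediction is empty, over all pixels.
    """
    x = _as_batch(image)
    preds = model.net.forward(x)
    if head not in preds:
        raise KeyError(f"model has no head {head!r}")
    p = preds[head]
    sel = (p >= 0.5).astype(np.float32)
    if not sel.any():
        sel = np.ones_like(p)
    # pass 1: plain backprop for the CAM weights at cam_layer
    model.net.backward({head: sel}, accumulate=False)
    if cam_layer not in model.net.act_grads:
        raise KeyError(f"unknown layer {cam_layer!r}")
    grad_a = model.net.act_grads[cam_layer][0]          # (C, h, w)
    act = model.net.activations[cam_layer][0]
    weights = grad_a.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    cam_up = resize(cam.astype(np.float64), x.shape[2:], order=1,
                    mode="edge", anti_aliasing=False)
    # pass 2: guided backprop to the input
    d_in = model.net.backward({head: sel}, guided=True, accumulate=False)
    guided = d_in[0, 0].astype(np.float64)
    return AttributionMap(values=guided * cam_up, kind="guided_gradcam",
                          head=head, layer=cam_layer)


def avg_feature_map(model: SegModel, image: np.ndarray, layer: str = "bottleneck",
                    blend_alpha: float | None = None) -> AttributionMap:
    """Channel-mean activation of ``layer``, interpolated to input size."""
    x = _as_batch(image)
    model.net.forward(x)
    if layer not in model.net.activations:
        raise KeyError(f"unknown layer {layer!r}")
    act = model.net.activations[layer][0]
    mean = act.mean(axis=0).astype(np.float64)
    up = resize(mean, x.shape[2:], order=1, mode="edge", anti_aliasing=False)
    if blend_alpha is not None:
        img = x[0, 0].astype(np.float64)
        rng_img = img.max() - img.min()
        img_n = (img - img.min()) / rng_img if rng_img > 0 else img * 0
        rng_up = up.max() - up.min()
        up_n = (up - up.min()) / rng_up if rng_up > 0 else up * 0
        up = blend_alpha * up_n + (1 - blend_alpha) * img_n
    return AttributionMap(values=up, kind="avg_feature", head=None, layer=layer)


# --------------------------------------------------------------------------
# analytic receptive fields
# --------------------------------------------------------------------------

def _interval_back(lo: int, hi: int, layer: tuple[str, int]) -> tuple[int, int]:
    """Map an output index interval (inclusive) to the input interval of
    one layer."""
    kind, k = layer
    if kind == "conv":          # stride 1, same padding
        r = (k - 1) // 2
        return lo - r, hi + r
    if kind == "pool":          # kxk pooling, stride k
        return lo * k, hi * k + (k - 1)
    if kind == "up":            # kxk transposed conv, stride k
        return lo // k, hi // k
    raise ValueError(f"unsupported layer kind {kind!r}")


def rf_interval(layers, pixel: int) -> tuple[int, int]:
    """Inclusive input-index interval influencing one output index, for a
    forward-ordered chain of ('conv', k) / ('pool', k) / ('up', k) layers."""
    lo = hi = int(pixel)
    for layer in reversed(list(layers)):
        lo, hi = _interval_back(lo, hi, layer)
    return lo, hi


def backbone_layer_chain(backbone: BackboneConfig) -> list[tuple[str, int]]:
    """Deepest forward path of the encoder-decoder, head included."""
    chain: list[tuple[str, int]] = []
    for _ in range(backbone.depth - 1):
        chain += [("conv", 3), ("conv", 3), ("pool", 2)]
    chain += [("conv", 3), ("conv", 3)]                      # bottom level
    for _ in range(backbone.depth - 1):
        chain += [("up", 2), ("conv", 3), ("conv", 3)]
    chain += [("conv", 1)]                                   # 1x1 head
    return chain


def receptive_field(backbone: BackboneConfig, output_pixel: tuple[int, int],
                    image_shape: tuple[int, int]) -> ReceptiveField:
    """Input-pixel box that can influence one output pixel, clipped to the
    image."""
    chain = backbone_layer_chain(backbone)
    boxes = []
    for axis, (pix, size) in enumerate(zip(output_pixel, image_shape)):
        if not (0 <= pix < size):
            raise ValueError(f"output pixel {output_pixel} outside image {image_shape}")
        lo, hi = rf_interval(chain, pix)
        boxes.append((max(lo, 0), min(hi + 1, size)))  # half-open, clipped
    (r0, r1), (c0, c1) = boxes
    return ReceptiveField(center=(int(output_pixel[0]), int(output_pixel[1])),
                          box=(r0, r1, c0, c1))
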