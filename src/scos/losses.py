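"""Training objectives for the four task settings.

All segmentation and contour terms are soft Dice losses; a setting's
total is the plain (unweighted) sum of its terms:

* single-task:        L = -(1/N) sum_i Dice_i
* joint (SCOS):       L = -(1/N) sum_i (Dice_lung + Dice_heart + Dice_cord)_i
* + distance head:    L += mean_i mean_x (g(x) - p(x))^2
* + contour heads:    L += joint Dice loss over the three contour maps

The distance term is the squared error between predicted and true
distance maps; during training it is normalized per pixel (a pure
rescale) so its gradient into the shared backbone is commensurate with
the Dice terms — without it the regression term dominates early training
and the segmentation heads never leave their initialization basin.

Soft Dice uses 2*sum(p*t)/(sum(p)+sum(t)) with a small smoothing constant
so empty masks are stable during optimization; evaluation-time Dice (in
:mod:`scos.metrics`) uses hard masks and no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TaskSetting, get_setting
from .phantom import ORGANS

SMOOTH = 1e-6


@dataclass
class LossReport:
    total: float
    per_term: dict[str, float]


def soft_dice(pred: np.ndarray, truth: np.ndarray, smooth: float = SMOOTH) -> float:
    """Soft Dice of one prediction against one binary truth."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    return float((2.0 * (p * t).sum() + smooth) / (p.sum() + t.sum() + smooth))


def _dice_batch(pred, truth, smooth=SMOOTH, want_grad=False):
    """Per-sample soft Dice over a (N, ...) batch; optional d(dice)/d(pred)."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    n = p.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    a = 2.0 * inter + smooth
    b = p.sum(axis=axes) + t.sum(axis=axes) + smooth
    dice = a / b
    if not want_grad:
        return dice, None
    shape = (n,) + (1,) * (p.ndim - 1)
    grad = (2.0 * t * b.reshape(shape) - a.reshape(shape)) / (b ** 2).reshape(shape)
    return dice, grad


def loss_stl(pred: np.ndarray, truth: np.ndarray, smooth: float = SMOOTH) -> LossReport:
    """Negated mean Dice over the batch for a single organ."""
    dice, _ = _dice_batch(pred, truth, smooth)
    return LossReport(total=float(-dice.mean()), per_term={"dice": float(dice.mean())})


def loss_scos(preds: dict[str, np.ndarray], truths: dict[str, np.ndarray],
              smooth: float = SMOOTH) -> LossReport:
    """Negated mean of the summed per-organ Dice values."""
    per = {}
    total = 0.0
    for organ in ORGANS:
        if organ not in preds:
            raise KeyError(f"missing head {organ!r}")
        dice, _ = _dice_batch(preds[organ], truths[organ], smooth)
        per[f"dice_{organ}"] = float(dice.mean())
        total -= float(dice.mean())
    return LossReport(total=total, per_term=per)


def loss_distance(pred_map: np.ndarray, truth_map: np.ndarray,
                  per_pixel: bool = False) -> float:
    """Squared-error distance-map loss.

    ``per_pixel=False`` (default) is the plain sum of squared errors over
    pixels (mean over the batch if batched). ``per_pixel=True`` divides by
    the pixel count — the normalization the training loop uses so the
    regression term is commensurate with the Dice terms (a pure rescale
    of the same objective).
    """
    p = np.asarray(pred_map, dtype=np.float64)
    g = np.asarray(truth_map, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("shape mismatch")
    sse = float(((g - p) ** 2).sum())
    if p.ndim > 2:
        sse /= p.shape[0]
        npx = int(np.prod(p.shape[1:]))
    else:
        npx = p.size
    return sse / npx if per_pixel else sse


def compute_loss(setting: TaskSetting | str, preds: dict[str, np.ndarray],
                 targets: dict[str, np.ndarray], smooth: float = SMOOTH,
                 want_grad: bool = False):
    """Loss (and optionally d(loss)/d(head output)) for any task setting."""
    if isinstance(setting, str):
        setting = get_setting(setting)
    per: dict[str, float] = {}
    grads: dict[str, np.ndarray] = {}
    total = 0.0
    for head_name, _, _, loss_name in setting.heads:
        if head_name not in preds:
            raise KeyError(f"prediction for head {head_name!r} missing")
        if head_name not in targets:
            raise KeyError(f"target for head {head_name!r} missing")
        p, t = preds[head_name], targets[head_name]
        n = p.shape[0]
        if loss_name in ("dice_seg", "dice_contour"):
            dice, g = _dice_batch(p, t, smooth, want_grad=want_grad)
            term = float(dice.mean())
            key = head_name if loss_name == "dice_contour" else f"dice_{head_name}"
            per[key] = term
            total -= term
            if want_grad:
                grads[head_name] = -g / n
        elif loss_name == "sse_distance":
            term = loss_distance(p, t, per_pixel=True)
            per["distance"] = term
            total += term
            if want_grad:
                npx = int(np.prod(p.shape[1:]))
                grads[head_name] = -2.0 * (np.asarray(t, dtype=np.float64) - p) / (n * npx)
        else:  # pragma: no cover - settings define only the three loss kinds
            raise ValueError(f"unknown loss {loss_name!r}")
    report = LossReport(total=float(total), per_term=per)
    return (report, grads) if want_grad else report


def loss_tasks1(preds, targets, smooth: float = SMOOTH) -> LossReport:
    return compute_loss("TASKS1", preds, targets, smooth)


def loss_tasks2(preds, targets, smooth: float = SMOOTH) -> LossReport:
    return compute_loss("TASKS2", preds, targets, smooth)
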