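"""Image preprocessing and rotation augmentation.

The pipeline mirrors common thoracic-CT practice: symmetric row cropping
to discard empty table/air rows, linear soft-tissue intensity windowing
(default -135..215 HU mapped to 0..255, with clamping outside the
window), and in-plane rotation used both to build rotated test sets and
as an online training augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import LabeledSlice


@dataclass(frozen=True)
class WindowSpec:
    hu_min: float = -135.0
    hu_max: float = 215.0
    out_min: float = 0.0
    out_max: float = 255.0

    def __post_init__(self):
        if not (self.hu_max > self.hu_min and self.out_max > self.out_min):
            raise ValueError("window bounds must be strictly ordered")


def crop_rows(image: np.ndarray, n_drop_each_side: int) -> np.ndarray:
    """Drop ``n_drop_each_side`` rows from the top and bottom."""
    if n_drop_each_side < 0:
        raise ValueError("n_drop_each_side must be >= 0")
    if image.shape[0] < 2 * n_drop_each_side + 1:
        raise ValueError(
            f"cannot drop {n_drop_each_side} rows per side from {image.shape[0]} rows")
    if n_drop_each_side == 0:
        return image.copy()
    return image[n_drop_each_side:-n_drop_each_side].copy()


def window_intensity(image: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Clamp to [hu_min, hu_max] and map linearly onto [out_min, out_max]."""
    v = np.clip(np.asarray(image, dtype=np.float64), spec.hu_min, spec.hu_max)
    scale = (spec.out_max - spec.out_min) / (spec.hu_max - spec.hu_min)
    return spec.out_min + (v - spec.hu_min) * scale


def rotate_sample(sample: LabeledSlice, angle_deg: float,
                  fill_value: float | None = None) -> LabeledSlice:
    """Rotate image (bilinear) and masks (nearest) about the image center.

    ``fill_value`` defaults to the image minimum (air). The rotation angle
    accumulates onto the slice's recorded angle.
    """
    if angle_deg == 0.0:
        return LabeledSlice(image=sample.image.copy(),
                            masks={k: v.copy() for k, v in sample.masks.items()},
                            angle_deg=sample.angle_deg, case_id=sample.case_id,
                            slice_index=sample.slice_index)
    fill = float(sample.image.min()) if fill_value is None else float(fill_value)
    img = ndimage.rotate(sample.image.astype(np.float64), angle_deg, reshape=False,
                         order=1, mode="constant", cval=fill).astype(np.float32)
    # all masks in one nearest-neighbour resampling pass (same source grid,
    # so disjointness is preserved)
    names = list(sample.masks)
    stack = np.stack([sample.masks[o] for o in names]).astype(np.uint8)
    rstack = ndimage.rotate(stack, angle_deg, axes=(1, 2), reshape=False,
                            order=0, mode="constant", cval=0)
    masks = {o: rstack[i].astype(bool) for i, o in enumerate(names)}
    return LabeledSlice(image=img, masks=masks,
                        angle_deg=sample.angle_deg + angle_deg,
                        case_id=sample.case_id, slice_index=sample.slice_index)


def random_rotation_augment(sample: LabeledSlice, rng: np.random.Generator,
                            range_deg: tuple[float, float] = (-30.0, 30.0)) -> LabeledSlice:
    """Draw an angle uniformly from ``range_deg`` and rotate the sample."""
    lo, hi = range_deg
    if lo > hi:
        raise ValueError("range_deg must be ordered")
    angle = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return rotate_sample(sample, angle)


def preprocess_slice(sample: LabeledSlice, spec: WindowSpec = WindowSpec(),
                     n_drop: int = 0) -> LabeledSlice:
    """Window the intensities (and optionally crop rows) of one slice."""
    img = window_intensity(sample.image, spec)
    masks = sample.masks
    if n_drop:
        img = crop_rows(img, n_drop)
        masks = {k: crop_rows(v, n_drop).astype(bool) for k, v in masks.items()}
    return LabeledSlice(image=img.astype(np.float32),
                        masks={k: v.copy() for k, v in masks.items()},
                        angle_deg=sample.angle_deg, case_id=sample.case_id,
                        slice_index=sample.slice_index)
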