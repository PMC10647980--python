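"""Auxiliary learning targets: distance map and contour map.

The distance map is a shape prior for a regression head: inside each
organ, the Euclidean distance of every pixel to the organ boundary,
normalized by that organ's maximum so each organ spans [0, 1], then
summed across organs into a single channel (organs are disjoint, so the
sum is a mosaic). The contour map is each organ's binary edge, taken as
the mask minus its 8-connected morphological erosion.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), dtype=bool)


def distance_map(masks: dict[str, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Per-organ max-normalized interior distance transform, summed."""
    arrs = list(masks.values()) if isinstance(masks, dict) else list(masks)
    if not arrs:
        raise ValueError("need at least one mask")
    shape = arrs[0].shape
    out = np.zeros(shape, dtype=np.float64)
    for m in arrs:
        if m.shape != shape:
            raise ValueError("masks must share one shape")
        if not m.any():
            continue
        edt = ndimage.distance_transform_edt(m)
        out += edt / edt.max()
    return out


def contour_map(mask: np.ndarray) -> np.ndarray:
    """Binary organ edge: mask AND NOT erode(mask, 3x3)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    return m & ~ndimage.binary_erosion(m, structure=_STRUCT8, border_value=0)
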