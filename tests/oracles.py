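"""Independent brute-force oracles used by the tests.

Deliberately naive: contour extraction by neighbour counting and
all-pairs distance matrices, O(n^2), no KD-trees, no shared code with
the package's metric implementations.
"""

import numpy as np


def brute_contour(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 8/26-neighbour
    (image border counts as background)."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    out = np.zeros_like(m)
    for idx in np.argwhere(m):
        sl = tuple(slice(i, i + 3) for i in idx)
        if not padded[sl].all():
            out[tuple(idx)] = True
    return out


def brute_distances(a_coords, b_coords, spacing=None):
    a = np.asarray(a_coords, dtype=float)
    b = np.asarray(b_coords, dtype=float)
    if spacing is not None:
        s = np.asarray(spacing, dtype=float)
        a = a * s
        b = b * s
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff ** 2).sum(-1)).min(axis=1)


def brute_surface_metrics(x_mask, y_mask, spacing=None):
    """(max_hd, hd95, asd) via all-pairs distances; inf triple if X empty."""
    x = np.asarray(x_mask, dtype=bool)
    y = np.asarray(y_mask, dtype=bool)
    if not x.any():
        return float("inf"), float("inf"), float("inf")
    cx = np.argwhere(brute_contour(x))
    cy = np.argwhere(brute_contour(y))
    dxy = brute_distances(cx, cy, spacing)
    dyx = brute_distances(cy, cx, spacing)
    pooled = np.concatenate([dxy, dyx])
    return (float(pooled.max()),
            float(np.percentile(pooled, 95)),
            float(pooled.sum() / len(pooled)))
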