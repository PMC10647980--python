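"""Segmentation evaluation metrics with explicit infinity handling.

Five quantities per (case, organ): Dice, maximum Hausdorff distance
(maxHD), 95th-percentile Hausdorff distance (95%HD), average surface
distance (ASD), and — across a set of cases — N(inf), the number of
cases whose prediction is empty while the truth is not (total
recognition failure; all surface distances are infinite there).

Surface distances are computed between *contour* pixels (mask minus its
8/26-connected erosion) as nearest-neighbour Euclidean distances,
optionally scaled by the voxel spacing. maxHD is the maximum, 95%HD the
linearly-interpolated 95th percentile, and ASD the symmetric mean of the
pooled directed distances. Metrics work identically on 2D masks and 3D
volumes; 3D evaluation can first keep only the largest 26-connected
component of each predicted organ, mirroring clinical post-processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .phantom import ORGANS


@dataclass
class MetricRecord:
    case_id: str
    organ: str
    dice: float
    max_hd: float
    hd95: float
    asd: float

    @property
    def is_inf(self) -> bool:
        return math.isinf(self.asd)


@dataclass
class SummaryStats:
    q1: float
    median: float
    q3: float
    mean: float
    n: int
    n_inf: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map (boundary inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(prob) >= threshold


def _contour(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return m
    struct = np.ones((3,) * m.ndim, dtype=bool)
    return m & ~ndimage.binary_erosion(m, structure=struct, border_value=0)


def _contour_coords(mask: np.ndarray, spacing=None) -> np.ndarray:
    coords = np.argwhere(_contour(mask)).astype(np.float64)
    if spacing is not None:
        coords *= np.asarray(spacing, dtype=np.float64)[: coords.shape[1]]
    return coords


def directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For every point in ``a`` (n,d), distance to its nearest point in ``b``."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be nonempty")
    d, _ = cKDTree(b).query(a, k=1)
    return np.atleast_1d(d)


def _pooled(x_mask, y_mask, spacing=None):
    cx = _contour_coords(x_mask, spacing)
    cy = _contour_coords(y_mask, spacing)
    dxy = directed_distances(cx, cy)
    dyx = directed_distances(cy, cx)
    return dxy, dyx


def _check(x_mask, y_mask):
    y = np.asarray(y_mask, dtype=bool)
    x = np.asarray(x_mask, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("mask shapes differ")
    if not y.any():
        raise ValueError("ground-truth mask is empty; metric undefined")
    return x, y


def max_hd(x_mask: np.ndarray, y_mask: np.ndarray, spacing=None) -> float:
    """Maximum of both directed nearest-contour distances; inf if X empty."""
    x, y = _check(x_mask, y_mask)
    if not x.any():
        return math.inf
    dxy, dyx = _pooled(x, y, spacing)
    return float(max(dxy.max(), dyx.max()))


def hd95(x_mask: np.ndarray, y_mask: np.ndarray, spacing=None) -> float:
    """95th percentile (linear interpolation) of the pooled distances."""
    x, y = _check(x_mask, y_mask)
    if not x.any():
        return math.inf
    dxy, dyx = _pooled(x, y, spacing)
    return float(np.percentile(np.concatenate([dxy, dyx]), 95))


def asd(x_mask: np.ndarray, y_mask: np.ndarray, spacing=None) -> float:
    """Average surface distance, symmetrized over both contours."""
    x, y = _check(x_mask, y_mask)
    if not x.any():
        return math.inf
    dxy, dyx = _pooled(x, y, spacing)
    return float((dxy.sum() + dyx.sum()) / (len(dxy) + len(dyx)))


def dice_coefficient(x_mask: np.ndarray, y_mask: np.ndarray) -> float:
    """Hard-mask Dice 2|X∩Y| / (|X| + |Y|); 1.0 when both masks are empty."""
    x = np.asarray(x_mask, dtype=bool)
    y = np.asarray(y_mask, dtype=bool)
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / denom


def n_inf(records) -> int:
    """Number of cases with infinite ASD (empty prediction, nonempty truth)."""
    return sum(1 for r in records if math.isinf(r.asd))


def largest_cc_3d(mask_volume: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component of a binary volume.

    Ties resolve to the component encountered first in raster scan order
    (smallest minimum linear voxel index). Empty input passes through.
    """
    m = np.asarray(mask_volume, dtype=bool)
    if m.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not m.any():
        return m.copy()
    labels, n = ndimage.label(m, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1  # argmax returns the first (raster-order) maximum
    return labels == keep


def evaluate_case(pred: dict[str, np.ndarray], truth: dict[str, np.ndarray],
                  case_id: str = "case", spacing=None) -> list[MetricRecord]:
    """All metrics for one case (2D slice or 3D volume), one record per organ.

    Organs whose ground truth is empty are skipped (no record): the
    metrics are undefined without a reference surface.
    """
    records = []
    for organ, y in truth.items():
        if not np.asarray(y, dtype=bool).any():
            continue
        x = np.asarray(pred[organ], dtype=bool)
        if x.shape != np.asarray(y).shape:
            raise ValueError(f"pred/truth shape mismatch for {organ!r}")
        if not x.any():
            records.append(MetricRecord(case_id, organ, dice=0.0, max_hd=math.inf,
                                        hd95=math.inf, asd=math.inf))
            continue
        dxy, dyx = _pooled(x, np.asarray(y, dtype=bool), spacing)
        pooled = np.concatenate([dxy, dyx])
        records.append(MetricRecord(
            case_id, organ,
            dice=dice_coefficient(x, y),
            max_hd=float(pooled.max()),
            hd95=float(np.percentile(pooled, 95)),
            asd=float(pooled.sum() / len(pooled)),
        ))
    return records


def evaluate(preds, truths, mode: str = "2d", spacing=None,
             postprocess: bool = False, case_ids=None) -> list[MetricRecord]:
    """Evaluate many cases.

    mode="2d": ``preds``/``truths`` are sequences of per-slice organ->mask
    dicts; one record per (slice, organ). mode="3d": sequences of
    organ->volume dicts; ``postprocess=True`` keeps only the largest
    connected component of each predicted organ first.
    """
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    if len(preds) != len(truths):
        raise ValueError("preds and truths differ in length")
    if case_ids is None:
        case_ids = [f"{mode}_{i:04d}" for i in range(len(preds))]
    records = []
    for cid, p, t in zip(case_ids, preds, truths):
        if mode == "3d" and postprocess:
            p = {organ: largest_cc_3d(m) for organ, m in p.items()}
        records.extend(evaluate_case(p, t, case_id=cid, spacing=spacing))
    return records


def summarize(values) -> SummaryStats:
    """Quartile summary over the finite values; infinities counted apart."""
    v = np.asarray([float(x) for x in values], dtype=np.float64)
    n = len(v)
    inf_count = int(np.isinf(v).sum())
    finite = v[np.isfinite(v)]
    if len(finite) == 0:
        nan = float("nan")
        return SummaryStats(nan, nan, nan, nan, n, inf_count)
    q1, med, q3 = np.percentile(finite, [25, 50, 75])
    return SummaryStats(float(q1), float(med), float(q3), float(finite.mean()),
                        n, inf_count)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "case_id": r.case_id, "organ": r.organ, "dice": r.dice,
        "max_hd": r.max_hd, "hd95": r.hd95, "asd": r.asd, "is_inf": r.is_inf,
    } for r in records])


def summarize_records(records, metric: str) -> dict[str, SummaryStats]:
    """Per-organ SummaryStats of one metric column."""
    out = {}
    for organ in ORGANS:
        vals = [getattr(r, metric) for r in records if r.organ == organ]
        if vals:
            out[organ] = summarize(vals)
    return out
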