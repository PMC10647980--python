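"""Synthetic thorax phantom generator.

Produces labeled 2D slices (and coherent 3D stacks) that mimic the spatial
layout of a thoracic CT section: two air-filled lung fields left and right
of the midline, a heart of soft-tissue intensity between and medial to
them, and a small spinal cord sitting in the canal of a high-intensity
vertebral ring on the posterior midline. Intensities are on a
Hounsfield-unit-like scale so that standard soft-tissue windowing is
meaningful.

Organs are analytic primitives (ellipses, discs, a midline stripe carve)
whose parameters are rotated *before* rasterization, so ground-truth masks
are exact at any in-plane angle — no label resampling error. Additive
Gaussian noise is applied to the intensity image only.

Everything is driven by a seeded ``numpy.random.Generator``; a fixed
config + seed reproduces bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

ORGANS = ("lung", "heart", "cord")
LABEL_CODES = {"lung": 1, "heart": 2, "cord": 3}


class PhantomGeometryError(ValueError):
    """Raised when the configured organ geometry cannot fit the image."""


def _default_intensities() -> dict[str, float]:
    # HU-like levels: air, aerated lung, soft tissue (body and heart blend,
    # as on real CT), cord slightly below muscle, dense vertebral bone.
    return {
        "background": -1000.0,
        "body": 40.0,
        "lung": -700.0,
        "heart": 40.0,
        "cord": 30.0,
        "vertebra": 400.0,
    }


@dataclass(frozen=True)
class PhantomConfig:
    image_height: int = 64
    image_width: int = 64
    lung_size_range: tuple[float, float] = (0.16, 0.21)   # fraction of width
    heart_size_range: tuple[float, float] = (0.095, 0.125)  # fraction of width
    cord_radius_range: tuple[float, float] = (2.0, 3.0)   # pixels
    jitter_scale: float = 1.0                             # center jitter sd, px
    noise_sd: float = 20.0                                # HU
    intensity_levels: dict[str, float] = field(default_factory=_default_intensities)
    rotation_range_deg: tuple[float, float] = (-30.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("lung_size_range", "heart_size_range", "cord_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got {(lo, hi)}")
        lo, hi = self.rotation_range_deg
        if not (-90.0 <= lo <= hi <= 90.0):
            raise ValueError("rotation_range_deg must lie within [-90, 90]")
        if self.image_height < 16 or self.image_width < 16:
            raise PhantomGeometryError("image too small for the thorax layout")
        # largest lung must fit inside the body outline
        if self.lung_size_range[1] > 0.23:
            raise PhantomGeometryError("lung_size_range upper bound too large to fit")
        if self.heart_size_range[1] > 0.16:
            raise PhantomGeometryError("heart_size_range upper bound too large to fit")
        if self.cord_radius_range[1] + 3.0 > 0.12 * self.image_width:
            raise PhantomGeometryError("cord/vertebra too large for image width")


@dataclass
class LabeledSlice:
    image: np.ndarray                 # (H, W) float32, HU-like
    masks: dict[str, np.ndarray]      # organ -> (H, W) bool
    angle_deg: float
    case_id: str = "case0"
    slice_index: int = 0

    def validate(self) -> None:
        for name, m in self.masks.items():
            if m.shape != self.image.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != image {self.image.shape}")
        names = list(self.masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"masks {a!r} and {b!r} overlap")

    def label_map(self) -> np.ndarray:
        lab = np.zeros(self.image.shape, dtype=np.uint8)
        for organ, code in LABEL_CODES.items():
            lab[self.masks[organ]] = code
        return lab


@dataclass
class LabeledVolume:
    slices: list[LabeledSlice]
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)  # (row, col, thickness) mm

    def image_volume(self) -> np.ndarray:
        return np.stack([s.image for s in self.slices])

    def mask_volume(self, organ: str) -> np.ndarray:
        return np.stack([s.masks[organ] for s in self.slices])

    def label_volume(self) -> np.ndarray:
        return np.stack([s.label_map() for s in self.slices])


# --------------------------------------------------------------------------
# analytic primitives
# --------------------------------------------------------------------------

def _grid(h: int, w: int):
    rr, cc = np.mgrid[0:h, 0:w]
    return rr.astype(np.float64), cc.astype(np.float64)


def _ellipse_mask(rr, cc, center, semi_axes, theta_rad=0.0):
    """Pixels inside a rotated ellipse; theta rotates the ellipse frame."""
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta_rad), np.sin(theta_rad)
    u = ct * dr + st * dc
    v = -st * dr + ct * dc
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _rotate_point(p, center, angle_rad):
    dr, dc = p[0] - center[0], p[1] - center[1]
    ct, st = np.cos(angle_rad), np.sin(angle_rad)
    return (center[0] + ct * dr - st * dc, center[1] + st * dr + ct * dc)


def _stripe_mask(rr, cc, anchor, half_width, angle_rad):
    """Infinite stripe of given half width around the (rotated) vertical
    midline passing through ``anchor``."""
    n = (np.sin(angle_rad), np.cos(angle_rad))  # normal of the rotated vertical line
    d = (rr - anchor[0]) * n[0] + (cc - anchor[1]) * n[1]
    return np.abs(d) <= half_width


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_slice(config: PhantomConfig, rng: np.random.Generator, *,
                   case_id: str = "case0", slice_index: int = 0,
                   angle_deg: float | None = None,
                   organ_scales: dict[str, float] | None = None) -> LabeledSlice:
    """Draw one labeled slice.

    ``angle_deg=None`` draws the rotation uniformly from the config range;
    passing a value fixes it. ``organ_scales`` multiplies organ sizes
    (used by :func:`generate_volume` to taper organs across slices; a
    scale of 0 omits the organ).
    """
    h, w = config.image_height, config.image_width
    j = config.jitter_scale
    if angle_deg is None:
        lo, hi = config.rotation_range_deg
        angle_deg = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    scales = {"lung": 1.0, "heart": 1.0, "cord": 1.0}
    if organ_scales:
        scales.update(organ_scales)

    # unrotated layout (row, col); sizes in pixels
    s_lung = rng.uniform(*config.lung_size_range) * w * scales["lung"]
    s_heart = rng.uniform(*config.heart_size_range) * w * scales["heart"]
    r_cord = rng.uniform(*config.cord_radius_range) * scales["cord"]
    # the left lung field sits a little higher than the right one, so the
    # box spanned by the two lung centroids has a stable vertical extent
    lung_rows = (0.42 * h, 0.50 * h)
    lung_cols = (0.27 * w, 0.73 * w)
    lung_centers = [
        (lung_rows[0] + rng.normal(0, j), lung_cols[0] + rng.normal(0, j)),
        (lung_rows[1] + rng.normal(0, j), lung_cols[1] + rng.normal(0, j)),
    ]
    heart_center = (
        0.5 * (lung_centers[0][0] + lung_centers[1][0]),
        0.5 * (lung_centers[0][1] + lung_centers[1][1]),
    )
    cord_center = (0.80 * h + rng.normal(0, 0.5 * j), 0.5 * w + rng.normal(0, 0.5 * j))
    body_center = (0.54 * h, 0.5 * w)
    body_axes = (0.42 * h, 0.45 * w)
    noise = rng.normal(0.0, config.noise_sd, size=(h, w))  # drawn before geometry use

    pivot = ((h - 1) / 2.0, (w - 1) / 2.0)
    th = np.deg2rad(angle_deg)
    rr, cc = _grid(h, w)

    body_c = _rotate_point(body_center, pivot, th)
    body = _ellipse_mask(rr, cc, body_c, body_axes, th)
    if not body.any():
        raise PhantomGeometryError("body outline does not intersect the image")

    lungs = np.zeros((h, w), dtype=bool)
    if scales["lung"] > 0:
        for lc in lung_centers:
            c = _rotate_point(lc, pivot, th)
            lungs |= _ellipse_mask(rr, cc, c, (1.4 * s_lung, s_lung), th)
        # concave medial border: carve the mediastinal stripe
        stripe = _stripe_mask(rr, cc, _rotate_point((0.5 * h, 0.5 * w), pivot, th),
                              0.10 * w, th)
        lungs &= ~stripe
        lungs &= body
    heart = np.zeros((h, w), dtype=bool)
    if scales["heart"] > 0:
        c = _rotate_point(heart_center, pivot, th)
        heart = _ellipse_mask(rr, cc, c, (0.9 * s_heart, 1.25 * s_heart), th)
        heart &= body
    cord = np.zeros((h, w), dtype=bool)
    vertebra = np.zeros((h, w), dtype=bool)
    if scales["cord"] > 0:
        c = _rotate_point(cord_center, pivot, th)
        outer = _ellipse_mask(rr, cc, c, (r_cord + 2.5, r_cord + 2.5))
        inner = _ellipse_mask(rr, cc, c, (r_cord + 0.8, r_cord + 0.8))
        vertebra = outer & ~inner & body
        cord = _ellipse_mask(rr, cc, c, (r_cord, r_cord)) & body

    # label priority: cord > heart > lung (later paint wins)
    lungs &= ~(heart | vertebra | cord)
    heart &= ~cord

    lv = config.intensity_levels
    img = np.full((h, w), lv["background"], dtype=np.float64)
    img[body] = lv["body"]
    img[lungs] = lv["lung"]
    img[vertebra] = lv["vertebra"]
    img[heart] = lv["heart"]
    img[cord] = lv["cord"]
    img += noise

    masks = {"lung": lungs, "heart": heart, "cord": cord}
    full_scale = all(scales[o] > 0 for o in ORGANS) and (not organ_scales)
    if full_scale:
        for organ in ORGANS:
            if not masks[organ].any():
                raise PhantomGeometryError(f"{organ} mask empty under this config")
    sl = LabeledSlice(image=img.astype(np.float32), masks=masks, angle_deg=float(angle_deg),
                      case_id=case_id, slice_index=slice_index)
    sl.validate()
    return sl


def generate_dataset(config: PhantomConfig, n_slices: int, rotated: bool,
                     seed: int | None = None) -> list[LabeledSlice]:
    """Generate independent slices; ``rotated=False`` forces angle 0."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for i in range(n_slices):
        angle = None if rotated else 0.0
        out.append(generate_slice(config, rng, case_id=f"case{i:04d}",
                                  slice_index=0, angle_deg=angle))
    return out


def generate_volume(config: PhantomConfig, n_slices: int, angle_deg: float,
                    case_id: str = "vol0", seed: int | None = None,
                    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)) -> LabeledVolume:
    """One coherent case: organ sizes taper smoothly along the stack.

    The cord runs through every slice; lungs and heart occupy a contiguous
    central run of slices (absent in the first and last slice), emulating
    apex-to-base anatomy. The same in-plane rotation applies to all slices.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # one set of per-case draws keeps the stack coherent
    case_rng_seed = int(rng.integers(0, 2 ** 31 - 1))
    slices = []
    for z in range(n_slices):
        t = z / (n_slices - 1)
        lung_scale = float(np.sqrt(max(0.0, 1.0 - (2 * t - 1) ** 2)))
        if lung_scale < 0.35:
            lung_scale = 0.0
        if 0.2 <= t <= 0.8:
            heart_scale = float(np.sin(np.pi * (t - 0.2) / 0.6))
            heart_scale = heart_scale if heart_scale >= 0.3 else 0.0
        else:
            heart_scale = 0.0
        srng = np.random.default_rng((case_rng_seed, z))
        slices.append(generate_slice(
            config, srng, case_id=case_id, slice_index=z, angle_deg=angle_deg,
            organ_scales={"lung": lung_scale, "heart": heart_scale, "cord": 1.0}))
    return LabeledVolume(slices=slices, spacing=spacing)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def write_volume_nifti(volume: LabeledVolume, image_path: str, label_path: str) -> None:
    """Write a volume as one image NIfTI plus one integer label NIfTI
    (0=background, 1=lung, 2=heart, 3=cord)."""
    sr, sc, st = volume.spacing
    affine = np.diag([sr, sc, st, 1.0])
    img = volume.image_volume().transpose(1, 2, 0)   # (H, W, Z)
    lab = volume.label_volume().transpose(1, 2, 0)
    nib.save(nib.Nifti1Image(img.astype(np.float32), affine), image_path)
    nib.save(nib.Nifti1Image(lab.astype(np.uint8), affine), label_path)


def read_volume_nifti(image_path: str, label_path: str) -> LabeledVolume:
    img = nib.load(image_path)
    lab = nib.load(label_path)
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 0, 1)
    codes = np.asarray(lab.dataobj).transpose(2, 0, 1)
    zooms = img.header.get_zooms()[:3]
    slices = []
    for z in range(data.shape[0]):
        masks = {organ: codes[z] == code for organ, code in LABEL_CODES.items()}
        slices.append(LabeledSlice(image=data[z], masks=masks, angle_deg=float("nan"),
                                   case_id=image_path, slice_index=z))
    return LabeledVolume(slices=slices, spacing=(float(zooms[0]), float(zooms[1]),
                                                 float(zooms[2])))
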