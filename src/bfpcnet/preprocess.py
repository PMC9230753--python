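"""Image augmentation module: normalization, weighted enhancement,
geometric augmentation, and augmentation-driven class balancing.

The weighted enhancement is the classic fundus background-subtraction
transform

    I_weight = alpha * I_org + beta * blur(I_org) + gamma

with defaults alpha=4, beta=-4, gamma=128 and a 63x63 Gaussian kernel of
sigma 10 px.  Because blur(I) tracks the slowly varying illumination
field, the transform flattens lighting and recentres the image on gray
128 while amplifying vessels and lesions.  The affine result is clipped
to [0, 255]; the blur uses symmetric (reflective) border padding so the
bright fundus rim does not acquire a dark halo.

Geometric augmentation is restricted to the pixel-exact dihedral ops
(90-degree rotations, horizontal/vertical flips); labels are invariant
under all of them, and both eyes of a patient receive the same op so the
left/right pairing keeps its meaning.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image
from scipy import ndimage

from .data_io import CLASSES, PatientRecord


@dataclass
class EnhanceParams:
    alpha: float = 4.0
    beta: float = -4.0
    gamma: float = 128.0
    kernel_h: int = 63
    kernel_w: int = 63
    sigma: float = 10.0

    def validate(self):
        for k in (self.kernel_h, self.kernel_w):
            if k <= 0 or k % 2 == 0:
                raise ValueError(f"kernel dimensions must be odd and positive, got {k}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


AUGMENT_KINDS = ("rotate", "flip_horizontal", "flip_vertical")


@dataclass(frozen=True)
class AugmentOp:
    kind: str
    angle_degrees: int = 0

    def __post_init__(self):
        if self.kind not in AUGMENT_KINDS:
            raise ValueError(f"unsupported augment kind {self.kind!r}")
        if self.kind == "rotate" and self.angle_degrees not in (90, 180, 270):
            raise ValueError("rotation angle must be 90, 180 or 270 degrees")


ALL_AUGMENT_OPS = (
    AugmentOp("rotate", 90), AugmentOp("rotate", 180), AugmentOp("rotate", 270),
    AugmentOp("flip_horizontal"), AugmentOp("flip_vertical"),
)


def _check_rgb(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    return arr


def normalize_image(image, size: int = 256, interpolation: str = "bilinear") -> np.ndarray:
    """Resize an RGB image to size x size, keeping the 8-bit range.

    ``bilinear`` uses Pillow's antialiased triangle filter (for integer
    downscale factors it agrees with block averaging to within one gray
    level); ``area`` uses the exact box average.
    """
    arr = _check_rgb(image)
    if size < 32:
        raise ValueError("target size must be >= 32 pixels")
    resamples = {"bilinear": Image.Resampling.BILINEAR, "area": Image.Resampling.BOX}
    if interpolation not in resamples:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    out = Image.fromarray(arr.astype(np.uint8)).resize(
        (size, size), resamples[interpolation])
    return np.asarray(out)


def gaussian_kernel(params: EnhanceParams | None = None) -> np.ndarray:
    """Dense 2-D Gaussian kernel of shape (kernel_h, kernel_w), sum 1."""
    params = params or EnhanceParams()
    params.validate()
    ys = np.arange(params.kernel_h, dtype=float) - (params.kernel_h - 1) / 2
    xs = np.arange(params.kernel_w, dtype=float) - (params.kernel_w - 1) / 2
    k = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * params.sigma ** 2))
    return k / k.sum()


def _gaussian_blur(channel: np.ndarray, params: EnhanceParams) -> np.ndarray:
    # separable: 1-D passes along each axis with symmetric reflection
    ys = np.arange(params.kernel_h, dtype=float) - (params.kernel_h - 1) / 2
    xs = np.arange(params.kernel_w, dtype=float) - (params.kernel_w - 1) / 2
    kh = np.exp(-ys ** 2 / (2 * params.sigma ** 2))
    kw = np.exp(-xs ** 2 / (2 * params.sigma ** 2))
    kh /= kh.sum()
    kw /= kw.sum()
    out = ndimage.correlate1d(channel, kh, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kw, axis=1, mode="reflect")


def weighted_enhance(image, params: EnhanceParams | None = None) -> np.ndarray:
    """Background-subtraction enhancement, clipped to the 8-bit range.

    A constant image maps to uniform gamma + (alpha+beta)*c; with the
    defaults (alpha = -beta) every constant maps to uniform 128.
    """
    params = params or EnhanceParams()
    params.validate()
    arr = _check_rgb(image).astype(float)
    out = np.empty_like(arr)
    for c in range(3):
        blur = _gaussian_blur(arr[..., c], params)
        out[..., c] = params.alpha * arr[..., c] + params.beta * blur + params.gamma
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_augment(image, op: AugmentOp) -> np.ndarray:
    """Pixel-exact dihedral transform of an H x W x 3 array."""
    arr = _check_rgb(image)
    if op.kind == "flip_horizontal":
        return arr[:, ::-1].copy()
    if op.kind == "flip_vertical":
        return arr[::-1, :].copy()
    return np.rot90(arr, k=op.angle_degrees // 90, axes=(0, 1)).copy()


# ---------------------------------------------------------------------------
# class balancing


def class_counts(records: list[PatientRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CLASSES}
    for r in records:
        for c, bit in zip(CLASSES, r.labels):
            counts[c] += int(bit)
    return counts


def balance_dataset(records: list[PatientRecord], targets: dict[str, int],
                    seed: int = 0) -> list[PatientRecord]:
    """Oversample under-represented classes by cloning records with random
    augmentation ops (and optionally downsample over-represented ones).

    Classes are processed in the fixed label order.  Because records are
    multi-label, a clone made for one class also raises the counts of its
    other labels; counts are recomputed as balancing proceeds, so the
    target is met exactly for single-label pools and treated as
    "at least target" when labels overlap.  Every clone stores its op
    list in ``provenance`` so the pixel transform is reproducible.
    """
    unknown = set(targets) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes in targets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = [copy.deepcopy(r) for r in records]

    # seeded downsampling first, where a target sits below the current count
    for ci, cls in enumerate(CLASSES):
        if cls not in targets:
            continue
        members = [i for i, r in enumerate(out) if r.labels[ci] == 1]
        excess = len(members) - targets[cls]
        if excess > 0:
            drop = set(rng.choice(members, size=excess, replace=False).tolist())
            out = [r for i, r in enumerate(out) if i not in drop]

    # oversample by augmentation clones
    for ci, cls in enumerate(CLASSES):
        if cls not in targets:
            continue
        pool = [r for r in out if r.labels[ci] == 1]
        need = targets[cls] - len(pool)
        if need > 0 and not pool:
            raise ValueError(f"class {cls} is empty; cannot augment to {targets[cls]}")
        for _ in range(need):
            src = pool[int(rng.integers(len(pool)))]
            op = ALL_AUGMENT_OPS[int(rng.integers(len(ALL_AUGMENT_OPS)))]
            clone = copy.deepcopy(src)
            base_ops = list(src.provenance[1]) if src.provenance[0] == "augmented" else []
            clone.provenance = ("augmented", tuple(base_ops + [op]))
            out.append(clone)
    return out


def materialize(image: np.ndarray, record: PatientRecord) -> np.ndarray:
    """Apply a record's recorded augmentation ops to its image pixels."""
    if record.provenance[0] != "augmented":
        return image
    for op in record.provenance[1]:
        image = apply_augment(image, op)
    return image
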