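"""Synthetic phantoms, mask families, and the Hadamard corruption model.

Everything downstream (generator inversion, band-limited completion, the
variational sampler) is exercised on images produced here, so each generator
is a pure, seeded function: identical arguments give bit-identical arrays.

Images are numpy arrays with intensities in [0, 1], shape (H, W) for
grayscale or (H, W, C) channel-last.  Masks use the convention
1 = observed pixel, 0 = missing pixel, so the corrupted observation is the
elementwise (Hadamard) product ``mask * clean``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fourier import lowpass_project

__all__ = [
    "MaskSpec", "NoiseParams", "CorruptedObservation",
    "DEFAULT_COVERAGE", "MASK_FAMILIES",
    "validate_image", "generate_phantom", "generate_bandlimited_phantom",
    "generate_mask", "mask_coverage", "corrupt",
]

#: Default fraction of the image area each mask family removes.
DEFAULT_COVERAGE = {
    "chin": 0.15,
    "square": 0.25,
    "vrect": 0.50,
    "bottom": 0.50,
    "freeform": 0.25,
}

MASK_FAMILIES = tuple(DEFAULT_COVERAGE)


@dataclass(frozen=True)
class MaskSpec:
    """Geometry family, target masked-area fraction, and seed for a mask."""

    family: str
    target_coverage: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in DEFAULT_COVERAGE:
            raise ValueError(
                f"unknown mask family {self.family!r}; "
                f"choose one of {MASK_FAMILIES}")
        cov = self.coverage
        if not 0.0 < cov < 1.0:
            raise ValueError("target_coverage must lie in (0, 1)")

    @property
    def coverage(self) -> float:
        if self.target_coverage is None:
            return DEFAULT_COVERAGE[self.family]
        return float(self.target_coverage)


@dataclass(frozen=True)
class NoiseParams:
    """Pixel- and perceptual-noise scales of the corruption model."""

    sigma_pixel: float = 0.05
    sigma_percept: float = 1.0

    def __post_init__(self):
        if self.sigma_pixel < 0 or self.sigma_percept < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class CorruptedObservation:
    """Observed (masked, noisy) image plus the mask and noise model."""

    observed: np.ndarray
    mask: np.ndarray
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


def validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ValueError("image must be 2-D or channel-last 3-D")
    if image.ndim == 3 and image.shape[-1] not in (1, 3):
        raise ValueError("channel count must be 1 or 3")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("image sides must be >= 8")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    return image


def _ellipse_inside(yy, xx, cy, cx, ay, ax, theta):
    """Boolean inside-test for a rotated ellipse on a pixel grid."""
    y = yy - cy
    x = xx - cx
    c, s = math.cos(theta), math.sin(theta)
    yr = c * y - s * x
    xr = s * y + c * x
    return (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0


def generate_phantom(height: int, width: int, complexity: int = 3,
                     seed: int = 0) -> np.ndarray:
    """Brain-like grayscale phantom: skull rim, interior, nested structures.

    ``complexity`` internal ellipses with distinct intensities sit inside a
    bright elliptical shell, with low-amplitude smooth texture on top.  The
    family is deliberately low-dimensional (a handful of geometric and
    intensity parameters) so a small decoder can learn it.
    """
    if height < 16 or width < 16:
        raise ValueError("phantom sides must be >= 16")
    if complexity < 1:
        raise ValueError("complexity must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, height), np.linspace(-1, 1, width), indexing="ij")
    img = np.full((height, width), 0.02)

    cy, cx = rng.uniform(-0.06, 0.06, size=2)
    theta0 = rng.uniform(-0.3, 0.3)
    ay, ax = rng.uniform(0.78, 0.9), rng.uniform(0.68, 0.8)
    outer = _ellipse_inside(yy, xx, cy, cx, ay, ax, theta0)
    inner = _ellipse_inside(yy, xx, cy, cx, 0.88 * ay, 0.86 * ax, theta0)
    img[outer] = 0.92                      # skull rim
    img[inner] = rng.uniform(0.28, 0.42)   # brain tissue

    # internal structures with well-separated intensities
    levels = rng.permutation(np.linspace(0.55, 0.95, complexity))
    for k in range(complexity):
        scale = 0.62 * (1.0 - 0.55 * k / max(complexity, 2))
        ecy = cy + rng.uniform(-0.25, 0.25) * scale
        ecx = cx + rng.uniform(-0.25, 0.25) * scale
        eay = scale * rng.uniform(0.35, 0.7)
        eax = scale * rng.uniform(0.35, 0.7)
        region = _ellipse_inside(yy, xx, ecy, ecx, eay, eax,
                                 rng.uniform(0, math.pi)) & inner
        img[region] = levels[k]

    texture = lowpass_project(rng.standard_normal((height, width)), 0.05)
    tmax = np.abs(texture).max()
    if tmax > 0:
        img = img + 0.02 * texture / tmax * inner
    return np.clip(img, 0.0, 1.0)


def generate_bandlimited_phantom(height: int, width: int,
                                 passband_fraction: float,
                                 seed: int = 0) -> np.ndarray:
    """Smooth phantom whose DFT is exactly zero outside the passband."""
    if height < 8 or width < 8:
        raise ValueError("phantom sides must be >= 8")
    rng = np.random.default_rng(seed)
    img = lowpass_project(rng.standard_normal((height, width)),
                          passband_fraction)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)   # affine, so band-limitation survives
    else:
        img = np.zeros_like(img)
    return img


def mask_coverage(mask: np.ndarray) -> float:
    """Fraction of pixels missing (mask value 0)."""
    mask = np.asarray(mask)
    return float((mask == 0).mean())


def _disk_stamp(mask, cy, cx, radius):
    h, w = mask.shape
    y0, y1 = max(0, int(cy - radius)), min(h, int(cy + radius) + 1)
    x0, x1 = max(0, int(cx - radius)), min(w, int(cx + radius) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1][(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = 0


def _chin_blob(height, width, target, rng):
    cy, cx = 0.72 * height, 0.50 * width
    n_harm = 4
    amps = rng.uniform(-0.06, 0.06, size=n_harm)
    phases = rng.uniform(0, 2 * math.pi, size=n_harm)
    yy, xx = np.mgrid[0:height, 0:width]
    ang = np.arctan2(yy - cy, xx - cx)
    wobble = 1.0 + sum(a * np.cos((k + 1) * ang + p)
                       for k, (a, p) in enumerate(zip(amps, phases)))
    dist = np.hypot(yy - cy, xx - cx)
    radius = math.sqrt(target * height * width / math.pi)
    mask = np.ones((height, width), dtype=np.uint8)
    for _ in range(4):   # rescale toward the target area
        blob = dist <= radius * wobble
        achieved = blob.mean()
        if achieved <= 0:
            radius *= 1.5
            continue
        if abs(achieved - target) < 0.002:
            break
        radius *= math.sqrt(target / achieved)
    mask[dist <= radius * wobble] = 0
    return mask


def _freeform_strokes(height, width, target, rng):
    mask = np.ones((height, width), dtype=np.uint8)
    radius = max(2, round(min(height, width) / 22))
    for _ in range(2000):
        if mask_coverage(mask) >= target:
            break
        cy = rng.uniform(radius, height - radius)
        cx = rng.uniform(radius, width - radius)
        direction = rng.uniform(0, 2 * math.pi)
        for _ in range(rng.integers(15, 40)):
            _disk_stamp(mask, cy, cx, radius)
            if mask_coverage(mask) >= target:
                break
            direction += rng.uniform(-0.6, 0.6)
            cy = np.clip(cy + 0.8 * radius * math.sin(direction), 0, height - 1)
            cx = np.clip(cx + 0.8 * radius * math.cos(direction), 0, width - 1)
    return mask


def generate_mask(spec: MaskSpec, height: int, width: int) -> np.ndarray:
    """Binary mask (1 = observed) for one of the five geometry families.

    bottom and vrect hit their target exactly up to row/column rounding;
    square is exact up to integer side rounding; chin and freeform are
    seeded irregular shapes rescaled/grown to within ~0.03 of the target.
    """
    target = spec.coverage
    rng = np.random.default_rng(spec.seed)
    mask = np.ones((height, width), dtype=np.uint8)
    if spec.family == "bottom":
        n_rows = round(target * height)
        if n_rows:
            mask[height - n_rows:, :] = 0
    elif spec.family == "vrect":
        n_cols = round(target * width)
        if rng.random() < 0.5:
            mask[:, :n_cols] = 0
        else:
            mask[:, width - n_cols:] = 0
    elif spec.family == "square":
        side = round(math.sqrt(target * height * width))
        if side > min(height, width):
            raise ValueError(
                f"square mask with coverage {target} does not fit a "
                f"{height}x{width} canvas")
        r0 = (height - side) // 2
        c0 = (width - side) // 2
        mask[r0:r0 + side, c0:c0 + side] = 0
    elif spec.family == "chin":
        mask = _chin_blob(height, width, target, rng)
    elif spec.family == "freeform":
        mask = _freeform_strokes(height, width, target, rng)
    return mask


def corrupt(clean: np.ndarray, mask: np.ndarray, noise: NoiseParams,
            seed: int = 0) -> CorruptedObservation:
    """Hadamard corruption: zero out masked pixels, add noise to the rest.

    Gaussian pixel noise (std ``noise.sigma_pixel``) is applied only where
    the mask is 1 — masked cells carry no information and stay exactly 0.
    The result is clipped to [0, 1].
    """
    clean = validate_image(clean)
    mask = np.asarray(mask)
    if mask.shape != clean.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {clean.shape[:2]}")
    m = mask.astype(float)
    if clean.ndim == 3:
        m = m[..., None]
    observed = clean * m
    if noise.sigma_pixel > 0:
        rng = np.random.default_rng(seed)
        observed = observed + rng.normal(
            0.0, noise.sigma_pixel, size=clean.shape) * m
    observed = np.clip(observed, 0.0, 1.0)
    return CorruptedObservation(observed=observed, mask=np.asarray(mask),
                                noise=noise, seed=seed)
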