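"""Deterministic perceptual feature extractor (hand-crafted proxy).

The perceptual likelihood term and the diversity statistic need a feature
map Phi.  Learned extractors (VGG-style LPIPS backbones) need pretrained
weights, so this package substitutes a fixed, fully deterministic proxy:

* a 3-level Gaussian pyramid (5x5 binomial blur, stride-2 subsampling);
* at every level, 4 orientation-selective 3x3 gradient kernels
  (0, 45, 90, 135 degrees), evaluated on the interior (valid) region so a
  constant image yields exactly zero response;
* each response grid normalized by its root-mean-square plus an epsilon.

Distances in this feature space are labelled ``perceptual_proxy``
throughout — they are not LPIPS and are never reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import correlate as _nd_correlate

from ._autodiff import Tensor, as_tensor

__all__ = ["FeatureStack", "perceptual_features", "orientation_responses",
           "feature_tensors", "stack_distance_t", "ORIENTATION_KERNELS"]

_BINOMIAL = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
GAUSS5 = np.outer(_BINOMIAL, _BINOMIAL) / 256.0

#: Edge-orientation selective kernels, keyed by the edge angle in degrees
#: (90 = vertical edge, i.e. horizontal intensity gradient).
ORIENTATION_KERNELS = {
    0: np.array([[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]]),
    45: np.array([[0.0, 1.0, 2.0], [-1.0, 0.0, 1.0], [-2.0, -1.0, 0.0]]),
    90: np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]),
    135: np.array([[2.0, 1.0, 0.0], [1.0, 0.0, -1.0], [0.0, -1.0, -2.0]]),
}

N_LEVELS = 3
_EPS = 1e-6


@dataclass(frozen=True)
class FeatureStack:
    """Tuple of normalized orientation-response grids (levels x angles,
    repeated per channel for color images)."""

    grids: tuple

    def distance(self, other: "FeatureStack") -> float:
        """Squared L2 distance across the whole stack."""
        if len(self.grids) != len(other.grids):
            raise ValueError("feature stacks have different layouts")
        total = 0.0
        for a, b in zip(self.grids, other.grids):
            if a.shape != b.shape:
                raise ValueError("feature stacks have different layouts")
            total += float(((a - b) ** 2).sum())
        return total


@lru_cache(maxsize=32)
def _blur_norm(shape) -> np.ndarray:
    """Blur response of the all-ones image: dividing by it renormalizes
    the zero-padded Gaussian at the borders, so constants stay constant
    through the pyramid."""
    return _nd_correlate(np.ones(shape), GAUSS5, mode="constant", cval=0.0)


def _check_image_size(shape):
    if shape[0] < 16 or shape[1] < 16:
        raise ValueError("perceptual features need images of at least 16x16")


def _channel_tensors(x_t: Tensor):
    if x_t.value.ndim == 2:
        return [x_t]
    return [x_t[:, :, c] for c in range(x_t.value.shape[2])]


def feature_tensors(x_t: Tensor) -> list[Tensor]:
    """Differentiable feature stack of a (H, W) or (H, W, C) tensor."""
    _check_image_size(x_t.value.shape)
    grids: list[Tensor] = []
    for channel in _channel_tensors(x_t):
        level = channel
        for li in range(N_LEVELS):
            for kernel in ORIENTATION_KERNELS.values():
                resp = level.conv2d(kernel)[1:-1, 1:-1]
                rms = (resp * resp).mean().sqrt()
                grids.append(resp / (rms + _EPS))
            if li < N_LEVELS - 1:
                shape = tuple(level.value.shape)
                level = (level.conv2d(GAUSS5)
                         / _blur_norm(shape)).downsample2()
    return grids


def perceptual_features(image: np.ndarray) -> FeatureStack:
    """Feature stack of a plain array (non-differentiable entry point)."""
    image = np.asarray(image, dtype=float)
    grids = feature_tensors(as_tensor(image))
    return FeatureStack(grids=tuple(g.value for g in grids))


def stack_distance_t(x_t: Tensor, reference: FeatureStack) -> Tensor:
    """Differentiable squared stack distance to a fixed reference stack."""
    total = as_tensor(0.0)
    for grid_t, ref in zip(feature_tensors(x_t), reference.grids):
        diff = grid_t - ref
        total = total + (diff * diff).sum()
    return total


def orientation_responses(image: np.ndarray) -> dict:
    """Raw (unnormalized) orientation responses at the finest level,
    evaluated on the interior region."""
    image = np.asarray(image, dtype=float)
    _check_image_size(image.shape)
    t = as_tensor(image if image.ndim == 2 else image[..., 0])
    return {angle: t.conv2d(k).value[1:-1, 1:-1]
            for angle, k in ORIENTATION_KERNELS.items()}
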