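"""Reconstruction quality metrics and the hyperparameter sweep harness.

RMSE is reported on the 0-255 intensity scale (matching how published
inpainting tables print it; configurable), PSNR as 20*log10(scale/RMSE)
capped at 100 dB for identical images, SSIM with the standard 11x11
Gaussian-weighted window (sigma 1.5, K1=0.01, K2=0.03), and perceptual
distance in the deterministic proxy feature space (column name
``perceptual_proxy`` — this is not LPIPS).

Because compositing pastes observed pixels back verbatim, full-image
metrics understate inpainting error; masked-region-only variants are
therefore reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .map_inference import ForwardConfig, LossWeights, MAPInpainter
from .perceptual import perceptual_features
from .priors import LatentPrior

__all__ = ["MetricsRecord", "DiversityRecord", "image_metrics",
           "diversity_score", "ablation_sweep", "DEFAULT_SWEEP_GRIDS",
           "PSNR_CAP_DB"]

PSNR_CAP_DB = 100.0

#: One-at-a-time grids of the hyperparameter ablation (five values per
#: weight; the package defaults are the minimum-perceptual-error cells).
DEFAULT_SWEEP_GRIDS = {
    "lambda_pixel": [1e-7, 1e-6, 1e-5, 1e-4, 1e-3],
    "lambda_percept": [1e7, 1e6, 1e5, 1e4, 1e3],
    "lambda_cosine": [1e-4, 1e-3, 1e-2, 1e-1, 1.0],
    "lambda_prior": [1e-4, 1e-3, 1e-2, 1e-1, 1.0],
}


@dataclass(frozen=True)
class MetricsRecord:
    """Similarity metrics between a reference and a candidate image."""

    rmse: float
    psnr: float
    ssim: float
    perceptual_proxy: float
    rmse_masked: float | None = None
    perceptual_proxy_masked: float | None = None
    scale: float = 255.0

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse, "psnr": self.psnr, "ssim": self.ssim,
            "perceptual_proxy": self.perceptual_proxy,
            "rmse_masked": self.rmse_masked,
            "perceptual_proxy_masked": self.perceptual_proxy_masked,
        }


@dataclass(frozen=True)
class DiversityRecord:
    """Mean pairwise perceptual-proxy distance among reconstructions."""

    n_samples: int
    mean_pairwise: float
    pair_distances: np.ndarray = field(repr=False)


def _psnr(rmse: float, scale: float) -> float:
    if rmse == 0.0:
        return PSNR_CAP_DB
    return float(min(20.0 * np.log10(scale / rmse), PSNR_CAP_DB))


def image_metrics(reference: np.ndarray, candidate: np.ndarray,
                  mask: np.ndarray | None = None,
                  scale: float = 255.0) -> MetricsRecord:
    """RMSE / PSNR / SSIM / perceptual-proxy record, optionally with
    masked-region-only RMSE and perceptual variants (mask = 0 cells)."""
    reference = np.asarray(reference, dtype=float)
    candidate = np.asarray(candidate, dtype=float)
    if reference.shape != candidate.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {candidate.shape}")
    diff = reference - candidate
    rmse = float(np.sqrt(np.mean(diff ** 2)) * scale)
    ssim = float(structural_similarity(
        reference, candidate, data_range=1.0, gaussian_weights=True,
        sigma=1.5, use_sample_covariance=False, win_size=11,
        channel_axis=2 if reference.ndim == 3 else None))
    perceptual = perceptual_features(reference).distance(
        perceptual_features(candidate))

    rmse_masked = perceptual_masked = None
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != reference.shape[:2]:
            raise ValueError("mask shape does not match the images")
        missing = mask == 0
        if missing.any():
            d2 = (diff ** 2)[missing] if reference.ndim == 2 \
                else (diff ** 2)[missing, :]
            rmse_masked = float(np.sqrt(np.mean(d2)) * scale)
        else:
            rmse_masked = 0.0
        m = (1.0 - mask.astype(float))
        m = m if reference.ndim == 2 else m[..., None]
        perceptual_masked = perceptual_features(reference * m).distance(
            perceptual_features(candidate * m))
    return MetricsRecord(rmse=rmse, psnr=_psnr(rmse, scale), ssim=ssim,
                         perceptual_proxy=perceptual,
                         rmse_masked=rmse_masked,
                         perceptual_proxy_masked=perceptual_masked,
                         scale=scale)


def diversity_score(samples: list[np.ndarray]) -> DiversityRecord:
    """Mean over all unordered pairs of the perceptual-proxy distance."""
    if len(samples) < 2:
        raise ValueError("diversity needs at least 2 samples")
    stacks = [perceptual_features(np.asarray(s, dtype=float))
              for s in samples]
    n = len(samples)
    pairs = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pairs[i, j] = pairs[j, i] = stacks[i].distance(stacks[j])
    mean = float(pairs[np.triu_indices(n, k=1)].mean())
    return DiversityRecord(n_samples=n, mean_pairwise=mean,
                           pair_distances=pairs)


def ablation_sweep(suite, generator, base_weights: LossWeights,
                   sweep_spec: dict, seed: int = 0,
                   prior: LatentPrior | None = None,
                   fwd: ForwardConfig | None = None,
                   map_iterations: int = 200,
                   learning_rate: float = 0.001) -> pd.DataFrame:
    """One-at-a-time sensitivity sweep over the loss weights.

    ``suite`` is a list of (clean image, CorruptedObservation) pairs;
    ``sweep_spec`` maps a LossWeights field name to its grid.  Each grid
    point reruns MAP inpainting on the whole suite with only that weight
    changed and reports mean masked-region RMSE and mean perceptual-proxy
    distance, one row per grid point.
    """
    if not suite:
        raise ValueError("sweep needs a non-empty fixture suite")
    rows = []
    for name, grid in sweep_spec.items():
        if not hasattr(base_weights, name):
            raise ValueError(f"unknown loss weight {name!r}")
        for value in grid:
            weights = base_weights.replace(**{name: value})
            rmses, percs = [], []
            for idx, (clean, obs) in enumerate(suite):
                est = MAPInpainter(generator=generator, prior=prior,
                                   weights=weights, forward_config=fwd,
                                   n_iter=map_iterations,
                                   learning_rate=learning_rate,
                                   random_state=seed + idx)
                est.fit(obs)
                rec = image_metrics(clean, est.composited_, mask=obs.mask)
                rmses.append(rec.rmse_masked)
                percs.append(rec.perceptual_proxy)
            rows.append({"weight": name, "value": value,
                         "mean_masked_rmse": float(np.mean(rmses)),
                         "mean_perceptual_proxy": float(np.mean(percs))})
    return pd.DataFrame(rows)
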