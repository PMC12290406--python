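"""Structured latent priors: mean, between-level cosine, and band-limited
intensity via Papoulis-Gerchberg completion.

The prior over the latent code omega factorizes into three terms whose
product becomes a weighted sum of penalties in the log domain:

* mean prior — a diagonal Gaussian N(mu, diag(sigma^2)) over every latent
  coordinate; penalty sum(((omega - mu)/sigma)^2).
* cosine prior — the sum over adjacent level pairs of the angle
  arccos(<w_i, w_{i+1}> / (||w_i|| ||w_{i+1}||)); zero when consecutive
  levels are collinear with positive alignment.
* intensity prior — the squared distance, on masked pixels only, between a
  candidate image and the Papoulis-Gerchberg completion of the corrupted
  observation (alternating projections between a centered frequency
  passband and data consistency on observed pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor
from .fixtures import CorruptedObservation
from .fourier import lowpass_project

__all__ = [
    "LatentPrior", "PGTrace",
    "mean_prior_loss", "cosine_prior_loss", "pg_complete",
    "intensity_prior_loss", "combined_log_prior",
    "mean_prior_loss_t", "cosine_prior_loss_t", "intensity_prior_loss_t",
]


@dataclass(frozen=True)
class LatentPrior:
    """Gaussian latent prior plus the band-limitation parameters.

    mu, sigma : (L, D) arrays — per-coordinate prior mean and std.
    passband_fraction : fraction of DFT coefficients the intensity prior
        treats as the signal's support.
    pg_max_iters, pg_tol : stopping rule of the alternating projections.
    angular_scale : reserved scale of the directional distribution over
        [0, 2*pi); unused by the default penalty.
    """

    mu: np.ndarray
    sigma: np.ndarray
    passband_fraction: float = 0.2
    pg_max_iters: int = 500
    pg_tol: float = 1e-7
    angular_scale: float = 1.0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if mu.shape != sigma.shape or mu.ndim != 2:
            raise ValueError("mu and sigma must be equal-shape (L, D) arrays")
        if np.any(sigma <= 0):
            raise ValueError("prior sigma must be positive elementwise")
        if not 0.0 < self.passband_fraction <= 1.0:
            raise ValueError("passband_fraction must lie in (0, 1]")
        if self.pg_tol < 0:
            raise ValueError("pg_tol must be >= 0")

    @property
    def latent_shape(self):
        return self.mu.shape

    @classmethod
    def standard(cls, latent_shape, **kwargs) -> "LatentPrior":
        L, D = latent_shape
        return cls(mu=np.zeros((L, D)), sigma=np.ones((L, D)), **kwargs)

    @classmethod
    def from_decoder(cls, decoder, **kwargs) -> "LatentPrior":
        """Empirical prior from the training-latent statistics of a fitted
        auto-decoder."""
        return cls(mu=decoder.latent_mean_.copy(),
                   sigma=decoder.latent_std_.copy(), **kwargs)


@dataclass(frozen=True)
class PGTrace:
    """Iteration record of one Papoulis-Gerchberg run."""

    iterates_used: int
    changes: np.ndarray = field(repr=False)
    converged: bool = False


def _check_latent_pair(omega, prior):
    omega = np.asarray(omega, dtype=float)
    if omega.shape != prior.mu.shape:
        raise ValueError(
            f"latent shape {omega.shape} does not match prior "
            f"{prior.mu.shape}")
    return omega


def mean_prior_loss(omega: np.ndarray, prior: LatentPrior) -> float:
    """sum(((omega - mu) / sigma)^2): Gaussian negative log density up to
    an additive constant and a factor 2."""
    omega = _check_latent_pair(omega, prior)
    return float((((omega - prior.mu) / prior.sigma) ** 2).sum())


def mean_prior_loss_t(omega_t: Tensor, prior: LatentPrior) -> Tensor:
    return (((omega_t - prior.mu) * (1.0 / prior.sigma)) ** 2).sum()


def cosine_prior_loss(omega: np.ndarray) -> float:
    """Sum of angles between adjacent latent levels, in [0, (L-1)*pi]."""
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2:
        raise ValueError("latent code must be an (L, D) matrix")
    norms = np.linalg.norm(omega, axis=1)
    for level, n in enumerate(norms):
        if n == 0.0:
            raise ValueError(f"latent level {level} is the zero vector")
    total = 0.0
    for i in range(omega.shape[0] - 1):
        cosine = omega[i] @ omega[i + 1] / (norms[i] * norms[i + 1])
        total += float(np.arccos(np.clip(cosine, -1.0, 1.0)))
    return total


def cosine_prior_loss_t(omega_t: Tensor) -> Tensor:
    L = omega_t.shape[0]
    total = as_tensor(0.0)
    for i in range(L - 1):
        a, b = omega_t[i], omega_t[i + 1]
        dot = (a * b).sum()
        na = (a * a).sum().sqrt()
        nb = (b * b).sum().sqrt()
        total = total + (dot / (na * nb)).arccos()
    return total


def pg_complete(obs: CorruptedObservation, prior: LatentPrior
                ) -> tuple[np.ndarray, PGTrace]:
    """Band-limited completion of the masked image by alternating
    projections.

    Starting from the observation (masked cells zero), each iteration
    (a) zeroes every Fourier coefficient outside the centered passband and
    (b) resets observed pixels to their observed values.  Both projections
    are onto convex sets, so the iterate-to-iterate change is eventually
    non-increasing; iteration stops when the max-abs change drops to
    ``prior.pg_tol`` or after ``prior.pg_max_iters`` sweeps.
    """
    mask = np.asarray(obs.mask)
    if mask.sum() == 0:
        raise ValueError("Papoulis-Gerchberg needs at least one observed "
                         "pixel")
    observed_cells = mask == 1
    x = np.asarray(obs.observed, dtype=float).copy()
    if x.ndim == 3:
        sel = observed_cells[..., None] & np.ones(x.shape, dtype=bool)
    else:
        sel = observed_cells
    data = x[sel]
    changes = []
    converged = False
    for _ in range(prior.pg_max_iters):
        y = lowpass_project(x, prior.passband_fraction)
        y[sel] = data
        change = float(np.abs(y - x).max())
        changes.append(change)
        x = y
        if change <= prior.pg_tol:
            converged = True
            break
    trace = PGTrace(iterates_used=len(changes),
                    changes=np.asarray(changes), converged=converged)
    return np.clip(x, 0.0, 1.0), trace


def _check_same_shape(a, b, mask):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = np.asarray(mask)
    if a.shape != b.shape or mask.shape != a.shape[:2]:
        raise ValueError("candidate, completion, and mask shapes disagree")
    return a, b, mask


def intensity_prior_loss(candidate: np.ndarray, pg_image: np.ndarray,
                         mask: np.ndarray) -> float:
    """Squared distance to the PG completion over masked cells only."""
    candidate, pg_image, mask = _check_same_shape(candidate, pg_image, mask)
    missing = (mask == 0).astype(float)
    if candidate.ndim == 3:
        missing = missing[..., None]
    return float((missing * (candidate - pg_image) ** 2).sum())


def intensity_prior_loss_t(candidate_t: Tensor, pg_image: np.ndarray,
                           mask: np.ndarray) -> Tensor:
    missing = (np.asarray(mask) == 0).astype(float)
    if candidate_t.value.ndim == 3:
        missing = missing[..., None]
    return (((candidate_t - pg_image) * missing) ** 2).sum()


def combined_log_prior(omega, candidate, pg_image, mask,
                       prior: LatentPrior, weights) -> float:
    """Weighted log prior: the density product becomes a negated weighted
    sum of the three penalties."""
    total = weights.lambda_prior * mean_prior_loss(omega, prior)
    total += weights.lambda_cosine * cosine_prior_loss(omega)
    total += weights.lambda_intensity * intensity_prior_loss(
        candidate, pg_image, mask)
    return -total
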