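"""Per-image Gaussian variational posterior over the latent code
(modified Bayes-by-Backprop).

Standard Bayes-by-Backprop places a Gaussian variational posterior over
network weights; the modification used here places it over the latent code
of a single corrupted image instead.  A diagonal Gaussian q with free mean
and log-std is fitted by minimizing

    KL(q || N(mu, diag(sigma^2)))  +  E_q[ weighted data losses ]

where the expectation is estimated with reparameterized Monte-Carlo draws
omega = mean + std * eps, eps ~ N(0, I), so gradients flow through both
parameters.  The KL term uses the Gaussian (mean) prior only; the cosine
and intensity priors, which have no closed-form KL, enter through the
expected-loss term.  Once fitted, any number of diverse reconstructions
can be drawn by decoding posterior samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Adam, Tensor, as_tensor
from .fixtures import CorruptedObservation
from .map_inference import (ForwardConfig, InpaintResult, LossWeights,
                            _percept_loss_t, _pixel_loss_t, composite_images)
from .priors import (LatentPrior, cosine_prior_loss_t, intensity_prior_loss_t,
                     pg_complete)

__all__ = ["VariationalParams", "kl_diag_gaussian", "BayesByBackprop",
           "bbb_fit", "sample_reconstructions"]


@dataclass(frozen=True)
class VariationalParams:
    """Diagonal Gaussian posterior parameters over the latent code."""

    mean: np.ndarray
    log_std: np.ndarray
    seed: int = 0
    elbo_trace: np.ndarray = field(default=None, repr=False)
    fitted: bool = False

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        log_std = np.asarray(self.log_std, dtype=float)
        if mean.shape != log_std.shape or mean.ndim != 2:
            raise ValueError(
                "mean and log_std must be equal-shape (L, D) arrays")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "log_std", log_std)

    @property
    def std(self) -> np.ndarray:
        return np.exp(self.log_std)


def kl_diag_gaussian(q: VariationalParams, prior: LatentPrior) -> float:
    """Closed-form KL(q || prior) between diagonal Gaussians, summed over
    every latent coordinate."""
    if q.mean.shape != prior.mu.shape:
        raise ValueError("variational and prior shapes disagree")
    if np.any(prior.sigma <= 0):
        raise ValueError("prior sigma must be positive")
    s = q.std
    kl = (np.log(prior.sigma) - q.log_std
          + (s ** 2 + (q.mean - prior.mu) ** 2) / (2.0 * prior.sigma ** 2)
          - 0.5)
    return float(kl.sum())


def _kl_t(mean_t: Tensor, log_std_t: Tensor, prior: LatentPrior) -> Tensor:
    s = log_std_t.exp()
    inv_two_var = 1.0 / (2.0 * prior.sigma ** 2)
    quad = (s * s + (mean_t - prior.mu) ** 2) * inv_two_var
    return (as_tensor(np.log(prior.sigma)) - log_std_t + quad - 0.5).sum()


def data_losses_t(omega_t: Tensor, obs: CorruptedObservation, generator,
                  weights: LossWeights, fwd: ForwardConfig,
                  pg_image) -> Tensor:
    """Weighted data-dependent losses at one latent draw (everything but
    the closed-form KL term)."""
    data = as_tensor(0.0)
    if weights.lambda_pixel > 0:
        data = data + weights.lambda_pixel * _pixel_loss_t(
            omega_t, obs, generator, fwd)
    if weights.lambda_percept > 0:
        data = data + weights.lambda_percept * _percept_loss_t(
            omega_t, obs, generator)
    if weights.lambda_cosine > 0:
        data = data + weights.lambda_cosine * cosine_prior_loss_t(omega_t)
    if weights.lambda_intensity > 0:
        data = data + weights.lambda_intensity * intensity_prior_loss_t(
            generator.decode_t(omega_t), pg_image, obs.mask)
    return data


class BayesByBackprop(BaseEstimator):
    """Fit the per-image Gaussian posterior by reparameterized gradients.

    fit(obs) runs ``n_iter`` Adam steps (default 500 at learning rate
    0.001) on KL + expected weighted loss with ``mc_samples`` Monte-Carlo
    draws per step.  The mean initializes at ``init_mean`` (e.g. a MAP
    solution) when given, else at the prior mean; log_std initializes at
    log(0.1 * prior sigma) so early iterations stay near the MAP regime.

    Fitted attributes: ``mean_``, ``log_std_``, ``elbo_trace_``.
    """

    def __init__(self, generator=None, prior=None, weights=None,
                 forward_config=None, n_iter=500, learning_rate=0.001,
                 mc_samples=1, init_mean=None, random_state=0):
        self.generator = generator
        self.prior = prior
        self.weights = weights
        self.forward_config = forward_config
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.mc_samples = mc_samples
        self.init_mean = init_mean
        self.random_state = random_state

    def fit(self, X: CorruptedObservation, y=None):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        obs = X
        prior = (self.prior if self.prior is not None
                 else LatentPrior.standard(tuple(self.generator.latent_shape)))
        weights = self.weights if self.weights is not None else LossWeights()
        fwd = (self.forward_config if self.forward_config is not None
               else ForwardConfig())
        L, D = prior.latent_shape

        mean0 = (np.asarray(self.init_mean, dtype=float).copy()
                 if self.init_mean is not None else prior.mu.copy())
        mean_t = Tensor(mean0, requires_grad=True)
        log_std_t = Tensor(np.log(0.1 * prior.sigma), requires_grad=True)

        pg_image = None
        if weights.lambda_intensity > 0:
            pg_image, _ = pg_complete(obs, prior)

        rng = np.random.default_rng(self.random_state)
        opt = Adam([mean_t, log_std_t], lr=self.learning_rate)
        trace = []
        # Polyak tail averaging: the objective is a Monte-Carlo estimate,
        # so single iterates fluctuate; the average over the last quarter
        # of the run is the returned posterior.
        avg_start = self.n_iter - max(1, self.n_iter // 4)
        avg_mean = np.zeros_like(mean0)
        avg_log_std = np.zeros_like(mean0)
        n_avg = 0
        for it in range(self.n_iter):
            opt.zero_grad()
            objective = _kl_t(mean_t, log_std_t, prior)
            for _ in range(self.mc_samples):
                eps = rng.standard_normal((L, D))
                omega_t = mean_t + log_std_t.exp() * eps
                objective = objective + data_losses_t(
                    omega_t, obs, self.generator, weights, fwd, pg_image
                ) * (1.0 / self.mc_samples)
            val = float(objective.value)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite variational objective at iteration {it}")
            trace.append(val)
            objective.backward()
            opt.step()
            if it >= avg_start:
                avg_mean += mean_t.value
                avg_log_std += log_std_t.value
                n_avg += 1

        self.mean_ = avg_mean / n_avg
        self.log_std_ = avg_log_std / n_avg
        # close the trace with the objective at the returned parameters
        # (fresh reparameterized draws from the same stream)
        mean_f = Tensor(self.mean_)
        log_std_f = Tensor(self.log_std_)
        closing = _kl_t(mean_f, log_std_f, prior)
        for _ in range(self.mc_samples):
            eps = rng.standard_normal((L, D))
            omega_t = mean_f + log_std_f.exp() * eps
            closing = closing + data_losses_t(
                omega_t, obs, self.generator, weights, fwd, pg_image
            ) * (1.0 / self.mc_samples)
        trace.append(float(closing.value))
        self.elbo_trace_ = np.asarray(trace)
        return self

    def params(self) -> VariationalParams:
        check_is_fitted(self, "mean_")
        return VariationalParams(mean=self.mean_, log_std=self.log_std_,
                                 seed=self.random_state,
                                 elbo_trace=self.elbo_trace_, fitted=True)

    def sample(self, obs: CorruptedObservation, n: int, seed: int = 0,
               composite: bool = True) -> list[InpaintResult]:
        return sample_reconstructions(self.params(), self.generator, obs,
                                      n, seed=seed, composite=composite)


def bbb_fit(obs: CorruptedObservation, generator, prior: LatentPrior,
            weights: LossWeights | None = None,
            fwd: ForwardConfig | None = None, iterations: int = 500,
            lr: float = 0.001, mc_samples: int = 1, seed: int = 0,
            init_mean: np.ndarray | None = None) -> VariationalParams:
    """Functional wrapper around :class:`BayesByBackprop`."""
    est = BayesByBackprop(generator=generator, prior=prior, weights=weights,
                          forward_config=fwd, n_iter=iterations,
                          learning_rate=lr, mc_samples=mc_samples,
                          init_mean=init_mean, random_state=seed)
    return est.fit(obs).params()


def sample_reconstructions(q: VariationalParams, generator,
                           obs: CorruptedObservation, n: int, seed: int = 0,
                           composite: bool = True) -> list[InpaintResult]:
    """Decode ``n`` independent posterior draws into reconstructions."""
    if not q.fitted:
        raise ValueError("variational parameters are not fitted")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n):
        omega = q.mean + q.std * rng.standard_normal(q.mean.shape)
        raw = generator.decode(omega)
        out = (composite_images(obs.observed, obs.mask, raw)
               if composite else raw)
        results.append(InpaintResult(
            latent=omega, raw_generated=raw, composited=out,
            per_term_losses={}, loss_trace=np.asarray([]), iterations=0,
            seed=seed))
    return results
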