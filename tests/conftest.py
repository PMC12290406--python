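"""Shared fixtures: a conjugate linear-Gaussian problem with its analytic
posterior, and one session-scoped trained decoder suite reused by the
end-to-end tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from latentpaint import (ForwardConfig, LatentPrior, LossWeights, NoiseParams,
                         corrupt, linear_generator_make)
from latentpaint.pipeline import (RunConfig, build_phantom_suite,
                                  make_generator, make_prior, make_weights)


@dataclass(frozen=True)
class ConjugateProblem:
    """Linear generator + Gaussian prior + pixel likelihood, with the
    closed-form posterior computed from the normal equations."""

    generator: object
    prior: LatentPrior
    obs: object
    clean: np.ndarray
    H: np.ndarray            # observed-row affine map latent -> pixels
    c: np.ndarray            # affine offset on observed pixels
    y: np.ndarray            # observed pixel values
    posterior_mean: np.ndarray
    posterior_precision: np.ndarray
    weights_map: LossWeights       # lambda_prior=0.5 -> exact neg log post
    weights_likelihood: LossWeights  # pixel term only (for the VI oracle)


@pytest.fixture(scope="session")
def conjugate_problem() -> ConjugateProblem:
    latent_shape, image_side = (2, 8), 16
    gen = linear_generator_make(latent_shape, (image_side, image_side),
                                seed=11)
    prior = LatentPrior.standard(latent_shape)
    rng = np.random.default_rng(7)
    clean = gen.decode(rng.standard_normal(latent_shape) * 0.8)
    mask = (rng.random((image_side, image_side)) < 0.7).astype(np.uint8)
    noise = NoiseParams(sigma_pixel=0.05)
    obs = corrupt(clean, mask, noise, seed=3)

    s = gen.output_scale
    sel = mask.ravel() == 1
    H = s * gen.A_[sel, :]
    c = 0.5 + s * gen.b_[sel]
    y = obs.observed.ravel()[sel]
    sp = noise.sigma_pixel
    precision = H.T @ H / sp ** 2 + np.eye(H.shape[1])
    mean = np.linalg.solve(precision, H.T @ (y - c) / sp ** 2)
    return ConjugateProblem(
        generator=gen, prior=prior, obs=obs, clean=clean, H=H, c=c, y=y,
        posterior_mean=mean, posterior_precision=precision,
        weights_map=LossWeights(lambda_prior=0.5, lambda_cosine=0.0,
                                lambda_pixel=1.0, lambda_percept=0.0),
        weights_likelihood=LossWeights(lambda_prior=0.0, lambda_cosine=0.0,
                                       lambda_pixel=1.0, lambda_percept=0.0))


@dataclass(frozen=True)
class DecoderSuite:
    config: RunConfig
    train: list
    test_pairs: list
    generator: object
    prior: LatentPrior
    weights: LossWeights
    fwd: ForwardConfig


@pytest.fixture(scope="session")
def decoder_suite() -> DecoderSuite:
    """200 training phantoms, a decoder trained on them, and 10 held-out
    corrupted phantoms with the centered square mask (~25% coverage)."""
    config = RunConfig(n_train=200, n_test=10, epochs=1500, seed=1,
                       iterations=400, lr=0.01)
    train, test_pairs = build_phantom_suite(config)
    generator = make_generator(config, train)
    return DecoderSuite(config=config, train=train, test_pairs=test_pairs,
                        generator=generator,
                        prior=make_prior(config, generator),
                        weights=make_weights(config),
                        fwd=ForwardConfig(nf=config.nf))
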