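"""Mean, cosine, and Papoulis-Gerchberg intensity priors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentpaint import (LatentPrior, LossWeights, NoiseParams,
                         combined_log_prior, corrupt, cosine_prior_loss,
                         generate_bandlimited_phantom, intensity_prior_loss,
                         lowpass_project, mean_prior_loss, pg_complete)


@pytest.fixture()
def seeded_latent():
    return np.random.default_rng(0).standard_normal((4, 8))


class TestMeanPrior:
    def test_zero_at_center_and_unit_offset(self):
        rng = np.random.default_rng(1)
        mu = rng.standard_normal((3, 4))
        sigma = rng.uniform(0.5, 2.0, (3, 4))
        prior = LatentPrior(mu=mu, sigma=sigma)
        assert mean_prior_loss(mu, prior) == 0.0
        assert mean_prior_loss(mu + sigma, prior) == pytest.approx(12.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        omega = rng.standard_normal((3, 4))
        mu = rng.standard_normal((3, 4))
        sigma = rng.uniform(0.5, 2.0, (3, 4))
        expected = 0.0
        for i in range(3):
            for j in range(4):
                expected += ((omega[i, j] - mu[i, j]) / sigma[i, j]) ** 2
        got = mean_prior_loss(omega, LatentPrior(mu=mu, sigma=sigma))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_positive_unless_centered(self, seeded_latent):
        prior = LatentPrior.standard((4, 8))
        assert mean_prior_loss(seeded_latent, prior) > 0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            LatentPrior(mu=np.zeros((2, 2)), sigma=np.zeros((2, 2)))


class TestCosinePrior:
    def test_collinear_levels_cost_zero(self):
        omega = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        assert cosine_prior_loss(omega) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair_costs_half_pi(self):
        omega = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert cosine_prior_loss(omega) == pytest.approx(np.pi / 2)

    def test_matches_per_pair_oracle(self, seeded_latent):
        expected = 0.0
        for i in range(3):
            a, b = seeded_latent[i], seeded_latent[i + 1]
            cosine = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            expected += np.arccos(np.clip(cosine, -1, 1))
        assert cosine_prior_loss(seeded_latent) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_level_named_in_error(self, seeded_latent):
        omega = seeded_latent.copy()
        omega[2] = 0.0
        with pytest.raises(ValueError, match="2"):
            cosine_prior_loss(omega)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 20), level=st.integers(0, 3),
           scale=st.floats(0.01, 100.0))
    def test_invariant_to_positive_level_rescaling(self, seed, level, scale):
        omega = np.random.default_rng(seed).standard_normal((4, 6))
        scaled = omega.copy()
        scaled[level] *= scale
        assert cosine_prior_loss(scaled) == pytest.approx(
            cosine_prior_loss(omega), abs=1e-8)

    def test_invariant_to_global_rotation(self, seeded_latent):
        rng = np.random.default_rng(9)
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        assert cosine_prior_loss(seeded_latent @ q) == pytest.approx(
            cosine_prior_loss(seeded_latent), abs=1e-9)

    def test_bounded(self, seeded_latent):
        assert 0.0 <= cosine_prior_loss(seeded_latent) <= 3 * np.pi


def _masked_obs(passband=0.2, masked_frac=0.4, side=32, seed=3):
    clean = generate_bandlimited_phantom(side, side, passband, seed=seed)
    rng = np.random.default_rng(4)
    mask = (rng.random((side, side)) >= masked_frac).astype(np.uint8)
    return clean, corrupt(clean, mask, NoiseParams(0.0), seed=0)


class TestPGComplete:
    def test_fully_observed_bandlimited_is_fixed_point(self):
        clean = generate_bandlimited_phantom(32, 32, 0.2, seed=1)
        obs = corrupt(clean, np.ones((32, 32), dtype=np.uint8),
                      NoiseParams(0.0))
        prior = LatentPrior.standard((1, 1), passband_fraction=0.2,
                                     pg_max_iters=5, pg_tol=1e-12)
        out, trace = pg_complete(obs, prior)
        assert np.abs(out - clean).max() < 1e-10
        assert trace.converged and trace.iterates_used == 1

    def test_completion_matches_least_squares_oracle(self):
        clean, obs = _masked_obs()
        prior = LatentPrior.standard((1, 1), passband_fraction=0.2,
                                     pg_max_iters=500, pg_tol=0.0)
        out, trace = pg_complete(obs, prior)
        missing = obs.mask == 0
        assert np.sqrt(np.mean((out - clean)[missing] ** 2)) <= 1e-3
        # direct solve for the passband coefficients via the projector
        n = clean.size
        proj = np.zeros((n, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            proj[:, i] = lowpass_project(e.reshape(clean.shape), 0.2).ravel()
        sel = obs.mask.ravel() == 1
        coeff, *_ = np.linalg.lstsq(proj[sel], obs.observed.ravel()[sel],
                                    rcond=None)
        direct = (proj @ coeff).reshape(clean.shape)
        assert np.sqrt(np.mean((out - direct) ** 2)) <= 1e-2

    def test_change_sequence_nonincreasing_after_first(self):
        _, obs = _masked_obs()
        prior = LatentPrior.standard((1, 1), passband_fraction=0.2,
                                     pg_max_iters=200, pg_tol=0.0)
        _, trace = pg_complete(obs, prior)
        diffs = np.diff(trace.changes[1:])
        assert np.all(diffs <= 1e-12)

    def test_empty_observed_set_rejected(self):
        clean = generate_bandlimited_phantom(16, 16, 0.3, seed=0)
        obs = corrupt(clean, np.zeros((16, 16), dtype=np.uint8),
                      NoiseParams(0.0))
        prior = LatentPrior.standard((1, 1))
        with pytest.raises(ValueError):
            pg_complete(obs, prior)


class TestIntensityPrior:
    def test_identity_and_empty_masked_set(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        mask = np.zeros((8, 8), dtype=np.uint8)
        assert intensity_prior_loss(a, a, mask) == 0.0
        assert intensity_prior_loss(a, b, np.ones_like(mask)) == 0.0

    def test_single_masked_cell(self):
        cand = np.zeros((8, 8))
        pg = np.zeros((8, 8))
        pg[3, 3] = 0.5
        mask = np.ones((8, 8), dtype=np.uint8)
        mask[3, 3] = 0
        assert intensity_prior_loss(cand, pg, mask) == pytest.approx(0.25)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            intensity_prior_loss(np.zeros((8, 8)), np.zeros((8, 9)),
                                 np.ones((8, 8)))


class TestCombinedLogPrior:
    def test_zero_weights_give_zero(self, seeded_latent):
        prior = LatentPrior.standard((4, 8))
        w = LossWeights(0.0, 0.0, 0.0, 0.0, 0.0)
        val = combined_log_prior(seeded_latent, np.zeros((8, 8)),
                                 np.zeros((8, 8)),
                                 np.ones((8, 8), dtype=np.uint8), prior, w)
        assert val == 0.0

    def test_recomposes_from_components(self, seeded_latent):
        prior = LatentPrior.standard((4, 8))
        rng = np.random.default_rng(1)
        cand, pg = rng.random((8, 8)), rng.random((8, 8))
        mask = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        w = LossWeights(lambda_prior=0.3, lambda_cosine=0.7,
                        lambda_pixel=0.0, lambda_percept=0.0,
                        lambda_intensity=0.0)
        expected = -(0.3 * mean_prior_loss(seeded_latent, prior)
                     + 0.7 * cosine_prior_loss(seeded_latent))
        got = combined_log_prior(seeded_latent, cand, pg, mask, prior, w)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_linear_in_weights(self, seeded_latent):
        prior = LatentPrior.standard((4, 8))
        rng = np.random.default_rng(2)
        cand, pg = rng.random((8, 8)), rng.random((8, 8))
        mask = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        w1 = LossWeights(0.1, 0.2, 0.0, 0.0, 0.3)
        w2 = LossWeights(0.2, 0.4, 0.0, 0.0, 0.6)
        a = combined_log_prior(seeded_latent, cand, pg, mask, prior, w1)
        b = combined_log_prior(seeded_latent, cand, pg, mask, prior, w2)
        assert b == pytest.approx(2 * a, rel=1e-12)
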