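"""Forward operator, loss terms, and MAP inversion."""

import numpy as np
import pytest

from latentpaint import (ForwardConfig, LossWeights, MAPInpainter,
                         NoiseParams, corrupt, forward_operator,
                         linear_generator_make, map_inpaint,
                         perceptual_features, perceptual_loss, pixel_loss,
                         total_loss)
from latentpaint.perceptual import orientation_responses
from latentpaint.priors import LatentPrior


class TestForwardOperator:
    def test_identity_when_disabled(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        ones = np.ones((16, 16), dtype=np.uint8)
        assert np.array_equal(forward_operator(img, ones, ForwardConfig()),
                              img)

    def test_masked_copy(self):
        img = np.full((16, 16), 0.7)
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[:8] = 1
        out = forward_operator(img, mask, ForwardConfig(nf=16))
        assert np.allclose(out[:8], 0.7) and np.allclose(out[8:], 0.0)

    def test_area_average_of_ones(self):
        img = np.ones((16, 16))
        ones = np.ones((16, 16), dtype=np.uint8)
        out = forward_operator(img, ones, ForwardConfig(nf=8))
        assert out.shape == (8, 8)
        assert np.allclose(out, 1.0)

    def test_nf_contract(self):
        with pytest.raises(ValueError):
            ForwardConfig(nf=4)
        with pytest.raises(ValueError):
            forward_operator(np.ones((16, 16)),
                             np.ones((16, 16), dtype=np.uint8),
                             ForwardConfig(nf=32))


class TestPixelLoss:
    def test_zero_when_generator_reproduces_observation(self):
        gen = linear_generator_make((2, 4), (16, 16), seed=0)
        omega = np.random.default_rng(1).standard_normal((2, 4)) * 0.5
        clean = gen.decode(omega)
        obs = corrupt(clean, np.ones((16, 16), dtype=np.uint8),
                      NoiseParams(0.0))
        assert pixel_loss(omega, obs, gen) == pytest.approx(0.0, abs=1e-20)

    def test_matches_scalar_loop_oracle(self):
        gen = linear_generator_make((2, 4), (16, 16), seed=3)
        rng = np.random.default_rng(2)
        omega = rng.standard_normal((2, 4)) * 0.5
        clean = gen.decode(rng.standard_normal((2, 4)) * 0.5)
        mask = (rng.random((16, 16)) < 0.6).astype(np.uint8)
        obs = corrupt(clean, mask, NoiseParams(0.05), seed=4)
        decoded = gen.decode(omega)
        expected = 0.0
        for i in range(16):
            for j in range(16):
                d = mask[i, j] * decoded[i, j] - obs.observed[i, j]
                expected += d * d
        expected /= 2 * 0.05 ** 2
        assert pixel_loss(omega, obs, gen) == pytest.approx(expected,
                                                            abs=1e-10)


class TestPerceptual:
    def test_constant_image_has_zero_features(self):
        # raw gradient responses vanish on a flat image; the epsilon in
        # the RMS normalization keeps the stack finite (float residue of
        # the border renormalization is amplified by 1/eps, hence 1e-9)
        resp = orientation_responses(np.full((32, 32), 0.6))
        assert all(np.abs(r).max() <= 1e-15 for r in resp.values())
        stack = perceptual_features(np.full((32, 32), 0.6))
        assert all(np.isfinite(g).all() and np.abs(g).max() < 1e-9
                   for g in stack.grids)

    def test_vertical_edge_maximizes_90_degree_channel(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        resp = orientation_responses(img)
        edge_col = 15 - 1   # valid-region offset
        strengths = {k: np.abs(v[:, edge_col]).max()
                     for k, v in resp.items()}
        assert strengths[90] == max(strengths.values())
        assert strengths[90] > strengths[0]

    def test_deterministic_and_symmetric(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        sa1, sa2 = perceptual_features(a), perceptual_features(a)
        assert all(np.array_equal(x, y)
                   for x, y in zip(sa1.grids, sa2.grids))
        assert sa1.distance(perceptual_features(b)) == pytest.approx(
            perceptual_features(b).distance(sa1))

    def test_distance_matches_manual_recomputation(self):
        rng = np.random.default_rng(6)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        sa, sb = perceptual_features(a), perceptual_features(b)
        manual = sum(float(((x - y) ** 2).sum())
                     for x, y in zip(sa.grids, sb.grids))
        assert sa.distance(sb) == pytest.approx(manual, abs=1e-10)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            perceptual_features(np.zeros((8, 8)))

    def test_perceptual_loss_zero_on_exact_reproduction(self):
        gen = linear_generator_make((2, 4), (16, 16), seed=7)
        omega = np.random.default_rng(3).standard_normal((2, 4)) * 0.5
        obs = corrupt(gen.decode(omega), np.ones((16, 16), dtype=np.uint8),
                      NoiseParams(0.0))
        assert perceptual_loss(omega, obs, gen) == pytest.approx(0.0,
                                                                 abs=1e-16)


class TestTotalLoss:
    def test_recomposition(self, conjugate_problem):
        p = conjugate_problem
        omega = np.random.default_rng(4).standard_normal((2, 8)) * 0.5
        w = LossWeights(lambda_prior=0.5, lambda_cosine=1e-3,
                        lambda_pixel=1.0, lambda_percept=2.0)
        val, terms = total_loss(omega, p.obs, p.generator, p.prior, w)
        recomposed = sum(t["weighted"] for t in terms.values())
        assert val == pytest.approx(recomposed, rel=1e-10)
        from latentpaint import cosine_prior_loss, mean_prior_loss
        assert terms["prior"]["raw"] == pytest.approx(
            mean_prior_loss(omega, p.prior), rel=1e-12)
        assert terms["cosine"]["raw"] == pytest.approx(
            cosine_prior_loss(omega), rel=1e-12)
        assert terms["pixel"]["raw"] == pytest.approx(
            pixel_loss(omega, p.obs, p.generator), rel=1e-12)

    def test_all_zero_weights(self, conjugate_problem):
        p = conjugate_problem
        w = LossWeights(0.0, 0.0, 0.0, 0.0, 0.0)
        omega = np.random.default_rng(0).standard_normal((2, 8))
        val, _ = total_loss(omega, p.obs, p.generator, p.prior, w)
        assert val == 0.0


class TestMAPInpainter:
    def test_matches_closed_form_posterior_mean(self, conjugate_problem):
        p = conjugate_problem
        res = map_inpaint(p.obs, p.generator, p.prior, p.weights_map,
                          iterations=2000, lr=0.01, seed=5)
        rel = (np.linalg.norm(res.latent.ravel() - p.posterior_mean)
               / np.linalg.norm(p.posterior_mean))
        assert rel <= 1e-2
        assert res.loss_trace[-1] <= res.loss_trace[0]

    def test_compositing_preserves_observed_pixels(self, conjugate_problem):
        p = conjugate_problem
        res = map_inpaint(p.obs, p.generator, p.prior, p.weights_map,
                          iterations=50, lr=0.01, seed=1)
        m = p.obs.mask == 1
        assert np.array_equal(res.composited[m], p.obs.observed[m])

    def test_deterministic(self, conjugate_problem):
        p = conjugate_problem
        a = map_inpaint(p.obs, p.generator, p.prior, p.weights_map,
                        iterations=30, lr=0.01, seed=2)
        b = map_inpaint(p.obs, p.generator, p.prior, p.weights_map,
                        iterations=30, lr=0.01, seed=2)
        assert np.array_equal(a.latent, b.latent)
        assert np.array_equal(a.loss_trace, b.loss_trace)

    def test_estimator_defaults_follow_published_settings(self):
        est = MAPInpainter()
        assert est.n_iter == 500
        assert est.learning_rate == pytest.approx(0.001)

    def test_alternating_levels_mode_runs(self, conjugate_problem):
        p = conjugate_problem
        est = MAPInpainter(generator=p.generator, prior=p.prior,
                           weights=p.weights_map, n_iter=40,
                           learning_rate=0.01, alternating_levels=True,
                           random_state=0)
        est.fit(p.obs)
        assert est.loss_trace_[-1] <= est.loss_trace_[0]

    def test_warm_start_runs_and_improves_over_init(self, conjugate_problem):
        p = conjugate_problem
        est = MAPInpainter(generator=p.generator, prior=p.prior,
                           weights=p.weights_map, n_iter=60,
                           learning_rate=0.01, warm_start_pg=True,
                           warm_start_iters=20, random_state=0)
        est.fit(p.obs)
        assert est.pg_image_ is not None
        assert est.loss_trace_[-1] <= est.loss_trace_[0]
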