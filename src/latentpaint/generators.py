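"""Differentiable generators G(omega) that the inversion framework inverts.

Two desk-scale backbones are provided behind one contract:

* :class:`LinearGenerator` — a seeded affine map from the flattened latent
  code to the image, followed by a clamped affine squashing into [0, 1].
  Because the map is affine wherever the clamp is inactive, the composition
  with the masking forward operator is affine too, which gives closed-form
  posterior oracles for the MAP and variational solvers.
* :class:`DecoderGenerator` — a small MLP decoder trained auto-decoder
  style (decoder weights and per-image latent codes optimized jointly by
  mean-squared reconstruction error).  It stands in for a large pretrained
  generator; the framework itself is generator-agnostic.

Both keep the layered latent structure (L levels x D dims per level) so the
between-level cosine prior remains meaningful; the full-scale default is
18 x 512, the desk-scale default 4 x 32.

The contract consumed by the inference modules is:
``latent_shape``, ``image_shape``, ``kind``, ``decode(omega) -> ndarray``
and ``decode_t(Tensor) -> Tensor`` (the differentiable path).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Adam, Tensor, as_tensor

__all__ = [
    "LinearGenerator", "DecoderGenerator", "generator_apply",
    "linear_generator_make", "decoder_train",
    "save_generator", "load_generator",
]


def _npix(image_shape) -> int:
    return int(np.prod(image_shape))


class LinearGenerator(BaseEstimator):
    """Seeded affine generator with a closed-form inversion oracle.

    G(omega) = clip(0.5 + output_scale * (A vec(omega) + b), 0, 1), with A
    and b drawn from a standard normal scaled by 1/sqrt(L*D).  With the
    default ``output_scale`` the clamp is inactive for latents of prior
    scale, so the generator is affine on the region the solvers explore.
    """

    kind = "linear"

    def __init__(self, latent_shape=(4, 32), image_shape=(16, 16),
                 output_scale=0.1, random_state=0):
        self.latent_shape = latent_shape
        self.image_shape = image_shape
        self.output_scale = output_scale
        self.random_state = random_state

    def fit(self, X=None, y=None):
        """Draw the seeded affine parameters (no data is consumed)."""
        L, D = self.latent_shape
        if L < 1 or D < 1:
            raise ValueError("latent_shape entries must be >= 1")
        n = _npix(self.image_shape)
        rng = np.random.default_rng(self.random_state)
        scale = 1.0 / np.sqrt(L * D)
        self.A_ = rng.standard_normal((n, L * D)) * scale
        self.b_ = rng.standard_normal(n) * scale
        return self

    def _check_latent(self, omega):
        omega = np.asarray(omega, dtype=float)
        if omega.shape != tuple(self.latent_shape):
            raise ValueError(
                f"latent shape {omega.shape} does not match generator "
                f"latent_shape {tuple(self.latent_shape)}")
        return omega

    def pre_clamp(self, omega: np.ndarray) -> np.ndarray:
        """Affine pre-activation A vec(omega) + b, reshaped to the image."""
        check_is_fitted(self, "A_")
        omega = self._check_latent(omega)
        return (self.A_ @ omega.ravel() + self.b_).reshape(self.image_shape)

    def decode_t(self, omega_t: Tensor) -> Tensor:
        check_is_fitted(self, "A_")
        L, D = self.latent_shape
        vec = omega_t.reshape(1, L * D)
        pre = vec @ self.A_.T + self.b_[None, :]
        out = (0.5 + self.output_scale * pre).clip(0.0, 1.0)
        return out.reshape(self.image_shape)

    def decode(self, omega: np.ndarray) -> np.ndarray:
        return self.decode_t(as_tensor(self._check_latent(omega))).value


class DecoderGenerator(BaseEstimator):
    """Small MLP decoder fitted auto-decoder style on an image corpus.

    fit(X) jointly optimizes the decoder weights and one free latent code
    per training image by Adam on mean squared reconstruction error.  The
    empirical latent statistics (``latent_mean_``, ``latent_std_``) are the
    natural latent prior for inverting held-out images.
    """

    kind = "decoder"

    def __init__(self, latent_shape=(4, 32), hidden_units=64, epochs=2000,
                 learning_rate=0.01, random_state=0):
        self.latent_shape = latent_shape
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y=None):
        images = [np.asarray(im, dtype=float) for im in X]
        if len(images) < 50:
            raise ValueError("auto-decoder training needs a corpus of >= 50 "
                             f"images, got {len(images)}")
        shape = images[0].shape
        if any(im.shape != shape for im in images):
            raise ValueError("corpus images must share one shape")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.image_shape = shape
        L, D = self.latent_shape
        n_lat, n_pix = L * D, _npix(shape)
        n_img = len(images)
        target = np.stack([im.ravel() for im in images])

        rng = np.random.default_rng(self.random_state)
        W1 = Tensor(rng.standard_normal((n_lat, self.hidden_units))
                    / np.sqrt(n_lat), requires_grad=True)
        b1 = Tensor(np.zeros(self.hidden_units), requires_grad=True)
        W2 = Tensor(rng.standard_normal((self.hidden_units, n_pix))
                    / np.sqrt(self.hidden_units), requires_grad=True)
        b2 = Tensor(np.zeros(n_pix), requires_grad=True)
        Z = Tensor(0.1 * rng.standard_normal((n_img, n_lat)),
                   requires_grad=True)
        params = [W1, b1, W2, b2, Z]
        opt = Adam(params, lr=self.learning_rate)
        curve = []
        for _ in range(self.epochs):
            opt.zero_grad()
            hidden = (Z @ W1 + b1.reshape(1, -1)).tanh()
            recon = (hidden @ W2 + b2.reshape(1, -1)).sigmoid()
            loss = ((recon - target) ** 2).mean()
            loss.backward()
            opt.step()
            curve.append(float(loss.value))
        if len(curve) > 1 and curve[-1] >= curve[0]:
            warnings.warn("decoder training loss did not decrease",
                          RuntimeWarning)
        self.W1_, self.b1_, self.W2_, self.b2_ = (
            W1.value, b1.value, W2.value, b2.value)
        self.latents_ = Z.value.reshape(n_img, L, D)
        self.loss_curve_ = np.asarray(curve)
        flat = Z.value
        self.latent_mean_ = flat.mean(axis=0).reshape(L, D)
        self.latent_std_ = np.maximum(flat.std(axis=0), 1e-3).reshape(L, D)
        return self

    def decode_t(self, omega_t: Tensor) -> Tensor:
        check_is_fitted(self, "W1_")
        L, D = self.latent_shape
        vec = omega_t.reshape(1, L * D)
        hidden = (vec @ self.W1_ + self.b1_[None, :]).tanh()
        out = (hidden @ self.W2_ + self.b2_[None, :]).sigmoid()
        return out.reshape(self.image_shape)

    def decode(self, omega: np.ndarray) -> np.ndarray:
        omega = np.asarray(omega, dtype=float)
        if omega.shape != tuple(self.latent_shape):
            raise ValueError(
                f"latent shape {omega.shape} does not match generator "
                f"latent_shape {tuple(self.latent_shape)}")
        return self.decode_t(as_tensor(omega)).value


def generator_apply(model, omega: np.ndarray) -> np.ndarray:
    """Decode a latent code into an image (functional form of ``decode``)."""
    return model.decode(omega)


def linear_generator_make(latent_shape, image_shape, seed: int = 0
                          ) -> LinearGenerator:
    return LinearGenerator(latent_shape=tuple(latent_shape),
                           image_shape=tuple(image_shape),
                           random_state=seed).fit()


def decoder_train(phantom_corpus, latent_shape, epochs: int, seed: int = 0,
                  hidden_units: int = 64, learning_rate: float = 0.01
                  ) -> DecoderGenerator:
    return DecoderGenerator(latent_shape=tuple(latent_shape),
                            hidden_units=hidden_units, epochs=epochs,
                            learning_rate=learning_rate,
                            random_state=seed).fit(phantom_corpus)


def save_generator(path, model) -> None:
    """Write a self-describing checkpoint (kind, shapes, parameters)."""
    if model.kind == "linear":
        np.savez(path, kind="linear",
                 latent_shape=np.asarray(model.latent_shape),
                 image_shape=np.asarray(model.image_shape),
                 output_scale=model.output_scale,
                 random_state=model.random_state,
                 A=model.A_, b=model.b_)
    elif model.kind == "decoder":
        np.savez(path, kind="decoder",
                 latent_shape=np.asarray(model.latent_shape),
                 image_shape=np.asarray(model.image_shape),
                 hidden_units=model.hidden_units,
                 random_state=model.random_state,
                 W1=model.W1_, b1=model.b1_, W2=model.W2_, b2=model.b2_,
                 latent_mean=model.latent_mean_,
                 latent_std=model.latent_std_,
                 loss_curve=model.loss_curve_)
    else:  # pragma: no cover - contract guard
        raise ValueError(f"unknown generator kind {model.kind!r}")


def load_generator(path):
    with np.load(path, allow_pickle=False) as data:
        kind = str(data["kind"])
        latent_shape = tuple(int(v) for v in data["latent_shape"])
        image_shape = tuple(int(v) for v in data["image_shape"])
        if kind == "linear":
            gen = LinearGenerator(latent_shape=latent_shape,
                                  image_shape=image_shape,
                                  output_scale=float(data["output_scale"]),
                                  random_state=int(data["random_state"]))
            gen.A_, gen.b_ = data["A"], data["b"]
            return gen
        if kind == "decoder":
            gen = DecoderGenerator(latent_shape=latent_shape,
                                   hidden_units=int(data["hidden_units"]),
                                   random_state=int(data["random_state"]))
            gen.image_shape = image_shape
            gen.W1_, gen.b1_ = data["W1"], data["b1"]
            gen.W2_, gen.b2_ = data["W2"], data["b2"]
            gen.latent_mean_ = data["latent_mean"]
            gen.latent_std_ = data["latent_std"]
            gen.loss_curve_ = data["loss_curve"]
            return gen
    raise ValueError(f"unknown generator kind {kind!r}")
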