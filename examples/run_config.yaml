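# Full experiment configuration for `latentpaint run`.
# Every random stage derives its seed from `seed`, so a config reproduces
# byte-identical metrics across runs.

out_dir: runs/demo
seed: 1

# fixture corpus: brain-like phantoms; held-out test images are never in
# the decoder's training set
n_train: 200
n_test: 10
height: 32
width: 32
complexity: 3            # nested internal structures per phantom

# corruption model
mask_family: square      # chin | square | vrect | bottom | freeform
mask_coverage: null      # null = family default (0.15/0.25/0.50/0.50/0.25)
sigma_pixel: 0.05        # additive Gaussian noise on observed pixels
sigma_percept: 1.0       # perceptual-likelihood scale

# generator
generator_kind: decoder  # decoder (trained MLP) | linear (analytic oracle)
latent_levels: 4
latent_dim: 16
hidden_units: 64
epochs: 1500
decoder_lr: 0.01

# latent prior / band-limited intensity prior
passband_fraction: 0.2
pg_max_iters: 500
pg_tol: 1.0e-07

# loss weights: "posterior" = exact negative-log-posterior calibration;
# "ablation" = the published hyperparameter-grid defaults
weights_mode: posterior
weight_overrides: {}

# forward model: 0 = no downsampling, else nf x nf area averaging
nf: 0

# inference
mode: map                # map | vi (vi additionally draws n_samples)
iterations: 400
lr: 0.01
mc_samples: 1
n_samples: 5
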