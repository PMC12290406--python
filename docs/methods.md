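# Methods

## Model

Inpainting is posed as posterior inference over the latent code of a
generative image model. The observation model for a clean image
`x ∈ [0,1]^{H×W}` and binary mask `M` (1 = observed, 0 = missing) is

    y = M ⊙ x + η_pixel,   η_pixel ~ N(0, σ_pixel² I) on observed cells,

optionally followed by `nf×nf` area-average downsampling (the forward
operator is then `op(x) = downsample(M ⊙ x)`). A second likelihood factor
compares images in a perceptual feature space Φ with scale `σ_percept`.
The image model is `x = G(ω)` for a differentiable generator with layered
latent code `ω ∈ R^{L×D}`.

The negative log posterior, up to constants, is the weighted objective

    L(ω) = λ_prior Σ((ω−μ)/σ)²                       (mean prior)
         + λ_cosine Σ_{i<L} arccos(ω_i·ω_{i+1} / ‖ω_i‖‖ω_{i+1}‖)
         + λ_pixel ‖op(G(ω)) − op(y)‖² / (2σ_pixel²)
         + λ_percept ‖Φ(M⊙G(ω)) − Φ(y)‖² / (2σ_percept²)
         [ + λ_intensity Σ_{masked} (G(ω) − x_PG)² ]

where `x_PG` is the Papoulis–Gerchberg completion of the observation.
MAP estimation minimizes `L` over `ω` by Adam; the variational step fits
a diagonal Gaussian `q(ω) = N(m, diag(s²))` minimizing
`KL(q ‖ N(μ, diag(σ²))) + E_q[data terms]` with reparameterized
Monte-Carlo gradients (`ω = m + s⊙ε`). The KL term covers only the
Gaussian mean prior; cosine and intensity priors, lacking a closed-form
KL, enter through the expected-loss term.

### Assumptions

* Masked pixels carry no information (they are exactly zero in the
  observation); noise acts only on observed pixels.
* The generator is deterministic and differentiable in `ω`; no density
  correction for the generator's Jacobian is applied — the prior is
  placed directly on `ω`. For deep generators the change-of-variables
  determinant is intractable, and omitting it is the standard practice in
  latent-space inversion.
* The cosine prior pairs **adjacent** levels only (`ω_1–ω_2`, `ω_2–ω_3`,
  …); all-pairs coupling would be quadratic in L and is not used.
* The intensity prior enters in two documented ways: as a warm-start
  target (the PG completion anchors the beginning of the latent search)
  and/or as an additive penalty with weight `λ_intensity` (default 0, the
  four-term objective; set it positive for the "full prior" mode).

## Papoulis–Gerchberg completion

The intensity prior's target is computed by alternating projections:
starting from the observation with masked cells zeroed, each sweep
(1) zeroes every DFT coefficient outside a centered passband holding
`passband_fraction` of all coefficients (side fraction `√f` per axis,
conjugate-symmetric so real images stay real), then (2) resets observed
pixels to their observed values. Both are projections onto convex sets,
so the iterate change is eventually non-increasing; iteration stops at
`pg_tol` max-abs change (default 1e-7) or `pg_max_iters` (default 500)
sweeps. For observations that are genuinely band-limited within the
passband the completion is exact: on a 32×32 phantom with 40% of pixels
masked it agrees with the direct least-squares solve for the passband
coefficients to ~1e-10 RMSE (test suite, criterion tests).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `L × D` | 4 × 32 (desk) / 18 × 512 (full scale) | layered latent code; desk default keeps the level structure meaningful while invertible in seconds |
| `σ_pixel` | 0.05 | pixel-noise std on [0,1] intensities (~13/255 gray levels) |
| `σ_percept` | 1.0 | perceptual-noise scale in proxy-feature units |
| `λ` (package defaults) | pixel 1e-6, percept 1e4, cosine 1e-3, prior 1e-3 | the minimum-perceptual-error cells of the one-at-a-time ablation grid (`DEFAULT_SWEEP_GRIDS`) |
| `λ` (posterior-calibrated) | pixel 1, percept 1, prior 0.5, cosine 1e-3 | `LossWeights.posterior_calibrated()`: with σ-scaled losses the objective is the exact negative log posterior; used for the synthetic experiments because the grid magnitudes target a learned feature scale, not this proxy |
| MAP/VI iterations, lr | 500, 0.001 | the full-scale optimization setting (Adam); the pipeline's desk-scale default is 400 iterations at lr 0.01 — Adam moves ≈ lr per coordinate per step, and the decoder's empirical latent scale is ~0.1–1, so lr 0.001 under-travels in 500 steps at this scale |
| `passband_fraction` | 0.2 | fraction of DFT coefficients the PG prior keeps |
| `nf` | 0 (off) | measurement downsampling; ≥ 8 when enabled |
| `mc_samples` | 1 | Monte-Carlo draws per variational step (standard practice) |

## Synthetic data

`generate_phantom` draws brain-like grayscale phantoms: a bright
elliptical shell (skull rim) around a darker interior with `complexity`
nested ellipses of well-separated intensities, plus low-amplitude smooth
texture. The family is deliberately low-dimensional (~15 geometric and
intensity parameters) so a ~70k-parameter decoder trained on 200 examples
can represent it. Mask families: `chin` (irregular blob, lower-middle,
15% area), `square` (centered, 25%), `vrect` (full-height side rectangle,
50%), `bottom` (bottom rows, 50%, exact to row rounding), `freeform`
(seeded brush strokes grown to the target). Coverages land within ±3
percentage points of target.

What the phantoms do **not** emulate: anatomical variability, MRI noise
statistics (Rician, bias fields), resolution, and the semantic richness
of natural images. A green end-to-end test therefore establishes that the
inversion machinery works and beats structure-free baselines on a learned
image family — not that it reaches published benchmark quality on FFHQ or
clinical MRI, which would require a GPU-scale generator and real data.

## Perceptual proxy

The learned perceptual extractors used at full scale need pretrained
weights, so the package substitutes a deterministic proxy: a 3-level
Gaussian pyramid (5×5 binomial blur, renormalized at borders so constants
stay constant; stride-2 subsampling) with four orientation-selective 3×3
gradient kernels (0°/45°/90°/135°) per level, evaluated on the interior
region, each response grid normalized by its RMS + 1e-6. Distances in
this space are labelled `perceptual_proxy` everywhere and are **not**
comparable to LPIPS numbers. The extractor is pluggable.

## Numerical choices

* **Gradients** — a minimal reverse-mode autodiff engine over numpy
  arrays powers every solver; all ops are finite-difference tested.
* **arccos clamp** — the cosine argument is clamped to [−1, 1] for the
  value (ties at ±1 are legitimate) and to ±(1 − 1e-7) for the gradient,
  keeping `1/√(1−x²)` finite at exact collinearity.
* **Generator head** — the affine generator maps pre-activations through
  `clip(0.5 + 0.1·pre, 0, 1)`; at prior scale the clamp is inactive, so
  the model is exactly affine where the solvers operate (the basis of the
  closed-form oracles). The decoder head is a sigmoid.
* **MAP returns the best iterate** seen (Adam is not monotone per step),
  so the final trace entry never exceeds the initial one.
* **Bayes-by-Backprop returns Polyak tail averages** (mean of the last
  quarter of iterations): the objective is a Monte-Carlo estimate, and
  selecting the best noisy iterate is biased. On the conjugate
  linear-Gaussian model the averaged fit recovers the analytic posterior
  mean to <1% and the diagonal-VI variances (`1/Λ_ii`, the optimum of a
  diagonal q against the full-covariance posterior) to <10%.
* **Initialization** — MAP: `ω ~ N(μ, σ²)` seeded; VI: mean at the MAP
  solution when available else `μ`, `log s = log(0.1 σ)`.
* **Compositing** (default on) pastes observed pixels over the decode, so
  observed regions are never altered; metrics are reported both full-image
  and masked-region-only because compositing makes full-image numbers
  insensitive to inpainting quality.
* **Degenerate inputs** — zero-norm latent levels are a contract error
  naming the level; an all-masked observation is rejected by PG; empty
  sweep corpora and sub-16×16 perceptual inputs are contract errors.
* **Determinism** — every stochastic routine takes an explicit seed;
  identical seeds give bit-identical arrays, and full pipeline runs are
  byte-identical across repeats.

## Design choices on genuinely open points

* The alternating-projection form of the PG step follows the classical
  algorithm (low-pass, then data consistency) with masked-region-zero
  initialization; the modification relative to the classical fixed-band
  setting is the configurable passband fraction and tolerance-based
  stopping.
* Joint optimization over all latent levels is the default; a per-level
  block-coordinate mode is available behind `alternating_levels=True` for
  experimentation.
* The arccos sum serves as the cosine prior's negative log density
  surrogate for a directional distribution over [0,2π); `angular_scale`
  is reserved for a parametric angular density but unused by default.
* No hyper-prior (e.g. a Gamma factor over the intensity-prior
  precision) is placed on the noise scales; they are fixed configuration.
* Mask geometries are representative constructions chosen to satisfy
  the stated area coverages, not reproductions of any particular
  benchmark's masks.

## Known limitations

* The auto-decoder MLP is a stand-in for a large pretrained generator;
  inversion quality on held-out images is bounded by its generalization.
* The perceptual proxy is hand-crafted; conclusions about perceptual
  fidelity transfer to learned metrics only qualitatively.
* The downsampling forward operator currently supports grayscale images
  (color images use `nf = 0`).
* PG completion of large contiguous masked regions converges slowly and
  is exact only for genuinely band-limited content.
* Benchmark-scale results (FFHQ/DIV2K/clinical MRI quality tables,
  learned-metric diversity scores) are out of desk-scale reach by
  construction; nothing in this package reproduces them.
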