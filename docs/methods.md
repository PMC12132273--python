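# Methods

## Model

The package implements a spiking, iterative variational autoencoder for
image patches.  The generative model is linear-Gaussian:

    p(x | z) = N(x; Phi z, I),      x in R^M,  z in N_0^K,

with a dictionary `Phi` (M pixels × K neurons, unit-norm columns when
normalization is on).  The approximate posterior and prior over the latent
spike count are Poisson, parameterized through real-valued membrane
potentials `u` via firing rates `r = exp(u)`.  Two Gaussian variants share
the same machinery: `gaussian` uses `q(z) = N(u, I)`, and `gaussian_relu`
rectifies the Gaussian sample, giving an atom at exactly zero.  The
single-sample variational free energy is

    F = 1/2 ||x - Phi z||^2 + beta * KL(q_u || p_{u0}),

with the Poisson KL in closed form `sum_i e^{u_i}(u_i - u0_i) - e^{u_i} +
e^{u0_i}` and the Gaussian KL `1/2 ||u - u0||^2`.  `beta` sets the
rate-distortion trade-off: the reconstruction term is the distortion, the KL
term the coding rate.

## Inference as natural-gradient dynamics

Inference is per-input optimization of `u`, not an amortized encoder pass.
The free-energy gradient uses one Monte-Carlo sample with the
straight-through estimator for the sampling step (`dz/dr ≈ I`), giving

    grad_u F ≈ e^u ⊙ [ -Phi^T (x - Phi z) + beta (u - u0) ].

Preconditioning by the inverse Fisher information of the Poisson posterior
(`G(u) = diag(e^u)` in the log-rate parameterization) cancels the leading
`e^u` factor, leaving circuit-like dynamics: a feedforward drive `Phi^T x`,
recurrent explaining-away `-Phi^T Phi z` carried by discrete spikes, and a
leak `-beta (u - u0)`.  Two discrete-time modes are implemented:

* **static prior** — the prior stays at `u0` and the leak is active;
* **online (rolling prior)** — each step's posterior becomes the next
  step's prior; in the single-update-per-time-point limit the KL term drops
  out of the update, leaving `u_{t+1} = u_t + eta [Phi^T x - W z_t]` with
  lateral weights `W = Phi^T Phi`.

For `eta = 1` the online update has an exactly equivalent multiplicative
form in rate space in which spiking neurons divisively suppress themselves
(`W_ii > 0`) and their similarly tuned neighbours — divisive normalization
emerging from the derivation rather than being inserted by hand.  The
equivalence is verified to float precision in the tests.

### Step size

The printed update has implicit `eta = 1`.  The scalar mean-field map
`u -> u + eta (b - e^u)` is linearly stable at its fixed point `u* = ln b`
only when `eta * b < 2`; the synthetic fixture produces feedforward drives
`b` up to ~8, so `eta = 1` oscillates between the clamp bounds and destroys
learning.  `eta` is therefore exposed everywhere (default 1.0 in
`DynamicsConfig`, matching the derivation) and the synthetic benchmark
configurations use `eta = 0.1`.  The rate-space form is only defined for
`eta = 1` and refuses other values.

### Numerical guards

Membrane potentials are clamped to `[-8, 8]` before exponentiation
(`e^8 ≈ 3000` spikes/step is far beyond any physiological rate and prevents
overflow).  Inference raises a divergence error naming the step index if a
potential becomes non-finite, rather than silently clamping — instability
should surface during training.  All computation is float64.

## Learning

Training unrolls `T_train` online inference steps per batch element and
minimizes the summed free energy of the whole trajectory (one optimizer
update per batch), backpropagating through the unrolled dynamics.  The
backward pass is written out by hand in NumPy as the exact reverse-mode
sweep of the straight-through surrogate graph (`z ~ z_detached + r -
r_detached`, so the pathwise Jacobian is `diag(r)` for Poisson, identity for
Gaussian, the rectifier mask for gaussian_relu); it is validated against
central finite differences of the deterministic (mean-field) unrolled
objective to 1e-9 relative error for all three families.  Summing (rather
than averaging) over steps follows the accumulated-gradient scheme; beta
values intended to be comparable across different `T_train` should scale
with it.

The optimizer is a hand-rolled Adam with cosine learning-rate decay.
When dictionary normalization is on, optimization is performed on the
product of unit spheres: the radial component of each column's gradient is
projected out before the Adam step and columns are renormalized afterwards.
This matters specifically for the spiking model: the expected reconstruction
gradient under Poisson sampling is `-(x - Phi r) r^T + Phi diag(r)`, whose
second (variance-penalty) term is exactly radial per column.  A plain
per-coordinate adaptive step rotates that radial pull into the tangent
space, and the resulting drift measurably corrupts the dictionary (a model
initialized at the generating dictionary drifts from recovery score 1.0 to
~0.5 within 15 epochs without the projection, and stays above 0.95 with
it).  Tangent projection is standard manifold (oblique-constraint) practice
in dictionary learning.

`u_init`, the resting prior potential, is a learnable K-vector initialized
at `ln 0.5` (about half a spike per step at rest).

The LCA baseline (locally competitive algorithm) is the deterministic,
non-spiking precursor: membrane dynamics `m <- m + eta [Phi^T x -
(W - I) s - m]` with soft-thresholded codes `s`, used for comparison only.

## Synthetic data

The generator inverts the model's own assumptions: `x = Phi* a + eps` with a
random unit-norm (or Gabor) dictionary `Phi*`, non-negative sparse codes `a
= Bernoulli(density) × Exponential(scale)`, and Gaussian pixel noise.
Defaults — M = 64 (8×8), K_true = 16, density 0.125, scale 2.0, sigma 0.05,
20 000 patches — give about two active generators per patch, identifiable
yet small enough that a full training run takes well under a minute on one
CPU.  What the fixture does *not* emulate: the 1/f spectral structure,
heavy-tailed statistics and spatial continuity of natural images, occlusion,
and dataset-scale overcompleteness (K >> M).  Passing the recovery and
sparsity benchmarks therefore demonstrates correctness of the inference and
learning machinery at desk scale, not natural-image performance.  About 12%
of fixture patches have an all-zero code (pure noise); these near-constant
patches are excluded from R² averages.

Also provided: Olshausen–Field-style frequency-domain whitening
(`|f| exp(-(|f|/f0)^4)`, `f0 = 0.8 ×` Nyquist) with per-patch mean removal
and per-dataset unit-variance scaling for natural image stacks; a bit-exact
big-endian IDX reader/writer for MNIST-format files; and a drifting-grating
generator for the contrast-latency probe.

## Evaluation

* **R²** between a patch and its reconstruction, computed per patch and
  averaged.  Two decoders: `sample` (reconstruct from the drawn spikes —
  the model's stochastic representation) and `mean` (reconstruct from the
  rates, deterministic/MAP-style).  At the fixture's scale the single-sample
  decode is dominated by Poisson noise (signal energy per patch is of order
  1–16 while the decode variance is `sum_i r_i`), so sampled R² is low or
  negative there; this is a property of the small-patch regime, and the
  deterministic decode is reported alongside it for landscape analyses.
* **Sparsity**: the fraction of latent entries exactly zero, always
  measured on sampled spikes.  Gaussian latents give exactly 0 by
  construction (continuous distributions have no atom at zero).
* **Update norm** `||u_{t+1} - u_t|| / eta`, the discrete proxy for the
  natural-gradient norm, tracking proximity to the attractor.
* **Convergence time**: the first step from which the (optionally smoothed)
  R² trace stays within a tolerance band for the remainder of the run;
  window 50 and tolerance 1e-3 by default, both configurable.  The spiking
  trajectory plateaus stochastically, so the acceptance analysis smooths
  with a 25-step moving average and uses a 0.02 band.
* **Landscape**: each model is a point `(R², sparsity)`; the score is the
  Euclidean distance to the ideal `(1, 1)` (perfect reconstruction from
  all-zero codes).  Negative R² is clipped to 0 with a warning.
* **Dictionary recovery**: Hungarian matching of learned to true columns
  maximizing mean |cosine|; invariant to permutation and sign.  Random
  unit vectors in R^64 score ≈ 0.1.
* **Contrast latency**: the model is driven with grating frames; latency is
  the first step at which the population rate crosses 50% of its final
  plateau (baseline-subtracted).  The 50% threshold is our
  operationalization of response latency.

## Benchmark configurations

The synthetic benchmarks use `K = 16`, `T_train = 16`, `eta = 0.1`, batch
256, Adam lr 1e-2 with cosine decay: 60 epochs for dictionary recovery
(beta = 0.1) and 20 epochs per model for the beta sweep
(beta in 0.5 × {0.5, 1, 2, 4}), sizes chosen so the full acceptance run
completes in a few minutes on one CPU.  The beta sweep measures test-set
spike sparsity on 1024 held-out patches, averaged over the last 50 of 200
online steps (the operating-point estimate is much less noisy than the
final step alone).

## Known limitations

* The training gradient uses the additive straight-through surrogate for
  the Poisson sampling path; a dedicated Poisson reparameterization
  gradient could reduce bias at large rates.
* The Gaussian variants fix unit posterior variance; learned variance is
  out of scope.
* Online-mode training is the only learning path (static-prior training is
  not implemented); inference supports both modes.
* Convergence of inference at small `eta` is slow (hundreds of steps for
  cross-talk suppression at the fixture scale), so sampled-decode R² keeps
  creeping long after the code support has stabilized.
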