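# Methods

## Model

The package implements neural cellular automata (NCA): a discrete dynamical
system on an `S x S` lattice whose cells carry `C` real channels, of which
the first `C_obs` are *observable* (compared to data) and the rest are
*hidden* latent channels the training is free to use as local memory. One
update step `x -> Φ(x, θ)` factorises into three stages:

1. **Perception.** Each of `K` fixed 3x3 kernels (identity, local average,
   Sobel gradients, nine-point Laplacian) is cross-correlated with every
   channel independently (depthwise), producing `z` of shape
   `S x S x C x K`. The kernels are discretised differential operators, so
   the NCA is structurally an explicit finite-difference integrator whose
   reaction term is learned. Kernels are never learned: the spatial
   operators stay interpretable and at most nine 3x3 kernels are linearly
   independent anyway.
2. **Per-pixel network.** At every pixel the flattened `C*K` perception
   values pass through one shared hidden layer:
   `f = W1 · u(W2 · z) + v`, with hidden width `H = 4C` by default and
   `u` either relu (`u(z) = (|z|+z)/2`), linear, or tanh.
3. **Stochastic gate and residual add.** Each increment is kept with
   probability `1 - p` (independent Bernoulli per element by default, or
   per pixel) and added to the state: `x' = x + σ ⊙ f`. The gate breaks
   global synchrony between cells; `p = 0` is fully deterministic and
   `p = 1` is the identity map.

Because the update is residual and the output layer is initialised to zero
(`W1 = 0`, `v = 0`, `W2` uniform on `±1/sqrt(C*K)`), a fresh NCA is exactly
the identity map — the "do nothing" start that avoids exploding/vanishing
BPTT gradients.

Boundary handling: `periodic` wraps reads; `fixed-zero` reads zeros outside
the lattice *and* re-zeroes the outermost ring after every step, so the
state vanishes at the boundary exactly rather than approximately.

### Coordinate and ordering conventions

Row index `i` increases downward, column `j` rightward; kernels are applied
as cross-correlations in those coordinates. The sign convention of the
gradient kernels is immaterial to training (weights absorb signs) but is
fixed by the printed matrices for reproducibility. The perception vector is
flattened channel-major (`c*K + k`) before `W2`; trajectory containers use
axes `(time, batch, row, col, channel)` everywhere.

## Differentiation

The environment provides no automatic-differentiation framework, so the
reverse-mode pass through the rollout is written analytically
(`ncalab._backprop`): the adjoint of depthwise cross-correlation is
cross-correlation with the 180°-rotated kernel (exact for both wrap and
zero-pad reads), the per-pixel network backward pass is two matmuls and an
activation derivative, the mask is a constant gate, and the fixed-zero ring
zeroing is a projection applied to the incoming gradient. Correctness is a
tested contract: `training.gradient_check` compares the analytic gradient
against central finite differences (step `1e-5`) on a random subset of
parameters and must agree to max relative error `1e-4`, with the mask
stream frozen when `p > 0`.

## Training

`training.train` implements transition-wise backpropagation through time.
Data `y[m, r]` (`m = 0..M` frames, `r = 0..R-1` trajectory copies) is
learned as transitions `x[m-1, r] -> y[m, r]`, each spanning `t` NCA steps.
Per epoch, the time and copy indices are independently shuffled into `B`
chunks; chunk gradients of the mean Euclidean loss (observable channels
only) are accumulated, scaled to unit global L2 norm (gradient
normalisation, with a zero-gradient epsilon guard), and applied in a single
Nadam update. Nadam is the classical bias-corrected Nesterov-Adam
recursion (`lr` default `1e-3`, `β1 = 0.9`, `β2 = 0.999`, `ε = 1e-8`),
implemented in-package and pinned by a hand-computed two-step unit test.
Note that with a constant gradient the bias-corrected Nesterov term
`(1-β1)g/(1-β1^t)` shrinks with `t`, so successive step magnitudes are
non-increasing; momentum accumulation shows up in the first-moment
accumulator, not the raw step size.

After each epoch the predicted states are propagated forward for every
trajectory copy except `reinit_batch` (default 0), which is reset to the
data with hidden channels zeroed. Propagation matters more than it first
appears: with pure re-initialisation every training transition starts from
hidden channels equal to zero, so a long free rollout — where hidden
channels accumulate over many windows — is far outside the training
distribution, and we observe learned rules that fit the data yet explode
numerically on unseen initial conditions. Carrying one copy's predictions
across epochs exposes training to evolved hidden states and suppresses
those runaway modes. When only one measured trajectory exists we therefore
train on two copies of it: one re-initialised, one propagated.

Two training-schedule knobs are exposed and recorded in configs:
`warmup_reinit_epochs` (re-initialise all copies for the first epochs) and
`select` (`"best"` returns the parameters at minimal recorded mean epoch
loss, the default; `"final"` returns the last-epoch parameters). For
propagated-copy runs the mean epoch loss includes the drifting propagated
states, which dominates early epochs; at small epoch budgets min-loss
selection can then return the untrained identity, and `select="final"` is
the appropriate choice. The recorded per-epoch loss is the arithmetic mean
over the transitions actually visited that epoch.

Training differentiates the Euclidean loss only (the default that worked
best across tasks); Hellinger, Bhattacharyya and Fourier-magnitude
distances are provided for evaluation. The mass-based losses shift each
observable channel by its minimum plus `1e-9` and normalise to unit sum
before applying the textbook definitions — a documented choice, since no
canonical extension to signed fields exists.

## Data generators

**Gray-Scott.** `task_data.simulate_gray_scott` integrates

    dA/dt = D_A ∇²A − A B² + α (1 − A)
    dB/dt = D_B ∇²B + A B² − (γ + α) B

by explicit Euler (`dt = 1`) on a periodic lattice, using the same
nine-point Laplacian kernel the NCA perceives with, so the learned rule and
the ground truth share one spatial operator. Defaults are the maze-pattern
parameters `D_A = 0.1`, `D_B = 0.05`, `α = 0.06230`, `γ = 0.06268`. A
stability guard rejects `dt·max(D) ≥ 1/3` (the nine-point Laplacian's
centre weight is −3). Initial conditions are seeded generators: `blobs`
(A = 1 background with rectangular B patches), `squares`, and
`high_frequency` (blobs plus checkerboard patches carrying ≥10% of spectral
energy above half-Nyquist, for generalisation tests on inputs never seen
during training).

**Measurement noise.** `corrupt_with_noise` applies
`ỹ = (1−ξ)y + ξη, η ~ U(min y, max y)` elementwise, with extrema taken
globally over the whole trajectory; `ξ = 0` is the exact identity.

**Image morphing.** `make_morph_sequence` builds fixed-boundary training
data from an RGBA image sequence: frames are area-averaged down to
`resolution` (default 60), embedded in a lattice padded by `pad` (default
16) cells of zeros, the final frame is repeated (default twice) so the end
state is trained as an attractor, and `R` copies (default 4) are given one
random spatial shift each (range ±8) so the rule cannot key on absolute
position. Small uniform noise (default ±0.005) is added to all data
frames; without it, gradients of the final self-transition diverge — the
noise carves a basin of attraction around the target. Image fixtures are
deterministic synthetic RGBA shapes (`disc`, `ring`, `cross`, `star`,
`glider`) generated in-package. Off-lattice rotations (`rotate_trajectory`,
symmetry evaluation) use bilinear interpolation with zero fill; multiples
of 90° are exact index permutations.

## Stability analyses

`stability.kappa` evaluates `κⁿ(x⁰, x̃⁰) = ‖x̃⁰‖ − ‖Φⁿ(x⁰+x̃⁰) − Φⁿ(x⁰)‖`
with both rollouts deterministic or sharing one frozen mask stream (a
stochastic objective would not compare like with like).
`adversarial_search` runs accepted-step gradient ascent/descent on κ from a
small uniform start (norm `1e-2`), halving the step on rejection so the
trace is monotone. `local_perturbation_map` perturbs each pixel's
observable channels (default magnitude 1.0), rolls out `n` steps and counts
final pixels whose observable max-change exceeds 0.1; counts are bounded by
the locality cone `(2n+1)²`. `symmetry_eval` scores rollouts from
transformed initial conditions against equally transformed targets.

## Problem sizes used by the test suite

The shipped checks run at desk scale, chosen so the full suite completes on
one CPU in minutes: heat-equation recovery trains a `C = 2` linear NCA on
`S = 16`, `M = 8`, `t = 1` data for 300 epochs; Gray-Scott dynamics
recovery trains a `C = 6` relu NCA on an `S = 32`, 512-step trajectory
sampled every `t = 16` (32 frames, duplicated into one re-initialised and
one propagated copy, `B = 2`) for 500 epochs, then scores a free 512-step
rollout from an unseen blob initial condition against the PDE, relative to
the untrained identity model; the noise-robustness comparison repeats that
run with `ξ = 0.8`. All randomness is seeded; reruns are bit-identical on
one platform.

## What the generators do and do not emulate

The synthetic tasks provide exact, noise-controlled ground truth with known
locality and symmetry structure — ideal for verifying that training
recovers a *known* local rule. They do not exercise: measurement operators
other than additive uniform noise, non-periodic PDE domains, anisotropic or
multiscale dynamics, long-horizon chaotic regimes (oscillatory Gray-Scott
parameter choices are deliberately out of scope), or real image statistics
(the shape fixtures are piecewise-constant with hard alpha edges). Passing
these suites shows the machinery is correct and can recover dynamics at
desk scale, not that NCA training is robust on experimental data.

## Known limitations

- Gradients are implemented for the Euclidean loss only; other losses are
  evaluation-only.
- The hand-written backward pass stores the full per-step tape; memory
  grows as `chunk * t * S² * C * (K + 2H)` and large instances need small
  chunks.
- Best-parameter selection by recorded mean loss is misleading when
  propagated copies dominate the mean early in training (see Training).
- Off-lattice rotations are bilinear; repeated 45° rotations accumulate
  interpolation blur.
- The explicit-Euler stability guard is a heuristic bound, not a proof of
  non-oscillatory behaviour for the reaction terms.
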