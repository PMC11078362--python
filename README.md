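# ncalab

Neural cellular automata (NCA) for learning spatio-temporal dynamics from
trajectory snapshots.

Many biological patterns — skin markings, developmental gradients, tissue
regeneration — emerge from purely local interactions, and the inverse
problem of finding local rules that produce an observed emergent behaviour
is hard. An NCA makes the classic cellular automaton differentiable: each
cell on an `S x S` lattice carries a vector of `C` real channels
(observable species concentrations plus hidden latent channels), and one
update step is

```
x' = x + σ ⊙ F(g * x)          F(z) = W1 · u(W2 · z) + v
```

where `g * x` is a depthwise stack of fixed 3x3 kernels (identity, local
average, Sobel gradients, nine-point Laplacian), `F` is a one-hidden-layer
network applied identically at every pixel (`H = 4C`), and `σ` is an
independent Bernoulli(1−p) gate that breaks global synchrony. Because the
kernels are discretised differential operators, the NCA with `p = 0` *is*
an explicit finite-difference PDE integrator whose reaction term is
learned. Training is backpropagation through time over the transitions
`y(m−1) → y(m)` of a snapshot trajectory, with mini-batched gradient
accumulation, global gradient normalisation and Nadam updates; the
reverse-mode pass through the rollout is implemented analytically in NumPy
and verified against finite differences.

The package ships the full experimental loop: a Gray-Scott
reaction-diffusion simulator (Turing patterns) and measurement-noise model,
an image-morphing task builder with synthetic shape fixtures, training, and
stability analyses (single-pixel perturbation maps, adversarial
perturbations of initial conditions via the κ functional, symmetry
scorecards).

## Worked example: recovering the heat equation

Train a 2-channel linear NCA on nine explicit-Euler snapshots of the
diffusion equation `∂t x = 0.2 ∇²x` on a 16x16 periodic lattice:

```python
import numpy as np
from ncalab import init_parameters, standard_kernels, UpdateConfig
from ncalab.core import step_array
from ncalab.training import TrainingData, TrainingConfig, train
from ncalab.kernels import KERNEL_MATRICES
from scipy import ndimage

S, M, d = 16, 8, 0.2
kernels = standard_kernels(["identity", "laplacian"])
x = np.random.default_rng(0).random((S, S))
frames = [x.copy()]
for _ in range(M):
    x = x + d * ndimage.correlate(x, KERNEL_MATRICES["laplacian"], mode="wrap")
    frames.append(x.copy())
data = TrainingData(y=np.stack(frames)[:, None, ..., None], t=1)

theta = init_parameters(C=2, K=2, activation="linear", rng=42)
theta_star, history = train(theta, data, TrainingConfig(epochs=300, seed=0), kernels)
print(f"initial loss {history[0]:.4f}, best loss {min(history):.6f}")

impulse = np.zeros((S, S, 2)); impulse[8, 8, 0] = 1.0
response = step_array(impulse, theta_star, kernels, UpdateConfig(p=0.0))
print(np.round(response[7:10, 7:10, 0], 4))
```

Output:

```
initial loss 0.6413, best loss 0.000154
[[0.05 0.1  0.05]
 [0.1  0.4  0.1 ]
 [0.05 0.1  0.05]]
```

The training loss falls four orders of magnitude below the identity
model's, and the learned one-step impulse response is exactly the explicit
Euler diffusion stencil `1 + 0.2 ∇²` (centre `1 − 0.6 = 0.4`, edge
`0.2·2/4 = 0.1`, corner `0.2·1/4 = 0.05`): the NCA has recovered the
underlying PDE discretisation from data alone.

## Command line

```bash
nca make-fixtures --out fixtures/              # synthetic RGBA shapes
nca simulate-pde  --config run.yaml --out sim/ # Gray-Scott trajectory
nca train         --config run.yaml --out run/ # model + loss.csv + metadata
nca rollout       --model run/model --steps 512 --ic-kind blobs --out roll/
nca stability     --model run/model --steps 16 --out stab/
nca eval-symmetry --model run/model --init-h5 sim/trajectory.h5 --steps 64 --out sym/
```

Configurations are YAML (`task`, `model`, `training`, `data` blocks); every
run directory records seeds and library versions for bit-identical reruns.

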