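"""NCA state, perception, per-pixel update network and update maps.

A neural cellular automaton (NCA) evolves an ``S x S`` lattice whose cells
carry ``C`` real channels.  One update step is

1. *perceive*: apply each fixed 3x3 kernel depthwise to every channel,
   producing an ``S x S x C x K`` perception field;
2. *increment*: at every pixel, feed the ``C*K`` perception values through a
   shared one-hidden-layer network ``f = W1 u(W2 z) + v``;
3. *mask*: gate each increment with an independent Bernoulli(1-p) draw and
   add the surviving increments to the state (a residual update).

The first ``C_obs`` channels are observable (compared to data during
training); the remainder are hidden latent channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .kernels import KernelSet

__all__ = [
    "LatticeState",
    "NCAParameters",
    "UpdateConfig",
    "ACTIVATIONS",
    "perceive",
    "increment",
    "sample_mask",
    "step",
    "rollout",
    "init_parameters",
    "enforce_boundary",
]

BOUNDARY_MODES = ("periodic", "fixed-zero")


def _relu(z: np.ndarray) -> np.ndarray:
    # u(z) = (|z| + z) / 2
    return (np.abs(z) + z) / 2.0


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0).astype(z.dtype)


def _linear(z: np.ndarray) -> np.ndarray:
    return z


def _linear_grad(z: np.ndarray) -> np.ndarray:
    return np.ones_like(z)


def _tanh_grad(z: np.ndarray) -> np.ndarray:
    return 1.0 - np.tanh(z) ** 2


ACTIVATIONS: dict[str, tuple] = {
    "relu": (_relu, _relu_grad),
    "linear": (_linear, _linear_grad),
    "tanh": (np.tanh, _tanh_grad),
}


@dataclass
class LatticeState:
    """State of the lattice: an ``S x S x C`` real field plus metadata."""

    values: np.ndarray
    C_obs: int
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError(f"state must be S x S x C, got shape {v.shape}")
        if v.shape[0] < 3:
            raise ValueError("lattice side S must be >= 3")
        if not 1 <= self.C_obs <= v.shape[2]:
            raise ValueError(f"need 1 <= C_obs <= C, got C_obs={self.C_obs}, C={v.shape[2]}")
        if not np.all(np.isfinite(v)):
            raise ValueError("state contains non-finite values")
        if self.boundary not in BOUNDARY_MODES:
            raise ValueError(f"boundary must be one of {BOUNDARY_MODES}")
        self.values = v
        if self.boundary == "fixed-zero":
            self.values = enforce_boundary(v, self.boundary)

    @property
    def S(self) -> int:
        return self.values.shape[0]

    @property
    def C(self) -> int:
        return self.values.shape[2]

    @property
    def observable(self) -> np.ndarray:
        return self.values[..., : self.C_obs]

    def copy(self) -> "LatticeState":
        return replace(self, values=self.values.copy())


@dataclass
class NCAParameters:
    """Per-pixel network weights shared across the lattice.

    ``W2`` maps the flattened perception vector (length ``C*K``, channel-major:
    index ``c*K + k``) to ``H`` hidden units; ``W1`` maps hidden units to ``C``
    channel increments; ``v`` is the output bias.  Default hidden width is
    ``H = 4C``.
    """

    W2: np.ndarray
    W1: np.ndarray
    v: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.W2 = np.asarray(self.W2, dtype=float)
        self.W1 = np.asarray(self.W1, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        H, CK = self.W2.shape
        C, H1 = self.W1.shape
        if H1 != H:
            raise ValueError(f"W1 hidden dim {H1} does not match W2 hidden dim {H}")
        if self.v.shape != (C,):
            raise ValueError(f"bias must have shape ({C},), got {self.v.shape}")
        if CK % C != 0:
            raise ValueError(f"W2 input dim {CK} is not a multiple of C={C}")
        for name, a in (("W2", self.W2), ("W1", self.W1), ("v", self.v)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def H(self) -> int:
        return self.W2.shape[0]

    @property
    def C(self) -> int:
        return self.W1.shape[0]

    @property
    def K(self) -> int:
        return self.W2.shape[1] // self.C

    def copy(self) -> "NCAParameters":
        return NCAParameters(self.W2.copy(), self.W1.copy(), self.v.copy(), self.activation)


@dataclass
class UpdateConfig:
    """Stochastic-mask configuration for the update step.

    ``p`` is the probability that an increment is *dropped*; ``p = 0`` gives a
    deterministic update and ``p = 1`` the identity map.  Granularity
    ``per-element`` draws an independent gate for every ``(i, j, c)``;
    ``per-pixel`` draws once per ``(i, j)`` and broadcasts over channels.
    """

    p: float = 0.0
    mask_granularity: str = "per-element"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"mask-off probability must lie in [0, 1], got {self.p}")
        if self.mask_granularity not in ("per-element", "per-pixel"):
            raise ValueError("mask_granularity must be 'per-element' or 'per-pixel'")


def enforce_boundary(values: np.ndarray, boundary: str) -> np.ndarray:
    """Zero the outermost ring of cells when the boundary is fixed-zero."""
    if boundary == "fixed-zero":
        values = values.copy()
        values[..., 0, :, :] = 0.0
        values[..., -1, :, :] = 0.0
        values[..., :, 0, :] = 0.0
        values[..., :, -1, :] = 0.0
    return values


def _correlate_mode(boundary: str) -> str:
    return "wrap" if boundary == "periodic" else "constant"


def perceive_array(
    x: np.ndarray, kernels: KernelSet, boundary: str = "periodic"
) -> np.ndarray:
    """Depthwise perception on a raw ``(..., S, S, C)`` array -> ``(..., S, S, C, K)``.

    Each kernel is cross-correlated with every channel independently; no
    channel mixing happens here.  Out-of-range reads wrap (periodic) or read
    zero (fixed-zero).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to perceive")
    lead = x.shape[:-3]
    S1, S2, C = x.shape[-3:]
    # Fold leading axes and channels together: kernels act per 2-D slice.
    flat = np.moveaxis(x, -1, -3).reshape(-1, S1, S2)
    mode = _correlate_mode(boundary)
    K = kernels.K
    out = np.empty((K, flat.shape[0], S1, S2))
    for k, mat in enumerate(kernels.stacked()):
        # size-1 kernel along the folded axis: no mixing across slices
        ndimage.correlate(flat, mat[None], mode=mode, cval=0.0, output=out[k])
    z = out.reshape(K, *lead, C, S1, S2)
    z = np.moveaxis(z, 0, -1)  # (..., C, S1, S2, K)
    z = np.moveaxis(z, -4, -2)  # (..., S1, S2, C, K)
    return np.ascontiguousarray(z)


def perceive_adjoint(
    gz: np.ndarray, kernels: KernelSet, boundary: str = "periodic"
) -> np.ndarray:
    """Adjoint of :func:`perceive_array`: ``(..., S, S, C, K)`` -> ``(..., S, S, C)``.

    The adjoint of cross-correlation with kernel ``g`` is cross-correlation
    with the 180-degree rotated kernel, in both wrap and zero-pad modes.
    """
    gz = np.asarray(gz, dtype=float)
    lead = gz.shape[:-4]
    S1, S2, C, K = gz.shape[-4:]
    mode = _correlate_mode(boundary)
    flat = np.moveaxis(gz, -1, 0)  # (K, ..., S, S, C)
    flat = np.moveaxis(flat, -1, -3).reshape(K, -1, S1, S2)
    acc = np.zeros_like(flat[0])
    for k, mat in enumerate(kernels.stacked()):
        acc += ndimage.correlate(flat[k], mat[::-1, ::-1][None], mode=mode, cval=0.0)
    gx = acc.reshape(*lead, C, S1, S2)
    return np.ascontiguousarray(np.moveaxis(gx, -3, -1))


def perceive(x: LatticeState, kernels: KernelSet):
    """Perception field of a lattice state, shape ``(S, S, C, K)``."""
    return perceive_array(x.values, kernels, x.boundary)


def increment(z: np.ndarray, theta: NCAParameters) -> np.ndarray:
    """Per-pixel network output ``f = W1 u(W2 z) + v`` on ``(..., S, S, C, K)``."""
    z = np.asarray(z, dtype=float)
    C, K = theta.C, theta.K
    if z.shape[-2:] != (C, K):
        raise ValueError(
            f"perception field trailing shape {z.shape[-2:]} does not match "
            f"parameters (C={C}, K={K})"
        )
    act, _ = ACTIVATIONS[theta.activation]
    zf = z.reshape(*z.shape[:-2], C * K)
    pre = zf @ theta.W2.T
    return act(pre) @ theta.W1.T + theta.v


def sample_mask(
    S: int, C: int, cfg: UpdateConfig, rng: np.random.Generator, lead: tuple = ()
) -> np.ndarray:
    """Bernoulli(1-p) gate field of shape ``lead + (S, S, C)`` (entries 0/1)."""
    if cfg.mask_granularity == "per-pixel":
        m = (rng.random(lead + (S, S, 1)) >= cfg.p).astype(float)
        return np.broadcast_to(m, lead + (S, S, C)).copy()
    return (rng.random(lead + (S, S, C)) >= cfg.p).astype(float)


def step_array(
    x: np.ndarray,
    theta: NCAParameters,
    kernels: KernelSet,
    cfg: UpdateConfig,
    rng: np.random.Generator | None = None,
    boundary: str = "periodic",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """One update step on a raw ``(..., S, S, C)`` array."""
    x = np.asarray(x, dtype=float)
    S, C = x.shape[-3], x.shape[-1]
    f = increment(perceive_array(x, kernels, boundary), theta)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite NCA increment: parameters are numerically unstable")
    if mask is None:
        if cfg.p == 0.0:
            mask = 1.0
        else:
            if rng is None:
                rng = np.random.default_rng(cfg.seed)
            mask = sample_mask(S, C, cfg, rng, lead=x.shape[:-3])
    out = x + mask * f
    return enforce_boundary(out, boundary)


def step(
    x: LatticeState,
    theta: NCAParameters,
    kernels: KernelSet,
    cfg: UpdateConfig,
    rng: np.random.Generator | None = None,
) -> LatticeState:
    """One NCA update step: ``x' = x + sigma * F(g * x)``."""
    out = step_array(x.values, theta, kernels, cfg, rng, boundary=x.boundary)
    return replace(x, values=out)


def rollout(
    x0: LatticeState,
    theta: NCAParameters,
    kernels: KernelSet,
    cfg: UpdateConfig,
    t: int,
    rng: np.random.Generator | None = None,
) -> list[LatticeState]:
    """Iterate the update map ``t`` times; returns ``t + 1`` states (first is ``x0``)."""
    if t < 0:
        raise ValueError("step count must be >= 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    traj = [x0.copy()]
    for n in range(t):
        try:
            traj.append(step(traj[-1], theta, kernels, cfg, rng))
        except FloatingPointError as exc:
            raise FloatingPointError(f"{exc} (at rollout step {n})") from None
    return traj


def init_parameters(
    C: int,
    K: int,
    H: int | None = None,
    activation: str = "relu",
    rng: np.random.Generator | int | None = None,
) -> NCAParameters:
    """Fresh parameters: random hidden weights, zero output layer and bias.

    ``W2`` is zero-mean uniform on ``[-s, s]`` with ``s = 1/sqrt(C*K)`` so that
    initial hidden pre-activations are O(1) for O(1) states; ``W1 = 0`` and
    ``v = 0`` make the freshly initialised NCA exactly the identity map.
    """
    if C < 1 or K < 1:
        raise ValueError("C and K must be >= 1")
    if H is None:
        H = 4 * C
    if H < 1:
        raise ValueError("hidden width H must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    scale = 1.0 / np.sqrt(C * K)
    W2 = rng.uniform(-scale, scale, size=(H, C * K))
    return NCAParameters(W2=W2, W1=np.zeros((C, H)), v=np.zeros(C), activation=activation)
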