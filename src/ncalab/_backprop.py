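"""Reverse-mode differentiation through NCA rollouts (backpropagation through time).

The update map is a shallow composition of linear and pointwise operations —
depthwise 3x3 correlation, a one-hidden-layer perceptron shared across
pixels, a Bernoulli gate and a residual add — so its exact reverse-mode pass
is written out directly here.  A forward rollout records a tape (perception
vectors, pre-activations, hidden activations, masks); the backward pass
replays it to accumulate gradients with respect to the network parameters
and, when requested, the initial state.  Correctness is pinned to central
finite differences by :func:`ncalab.training.gradient_check`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ACTIVATIONS, NCAParameters, enforce_boundary, perceive_adjoint, perceive_array
from .kernels import KernelSet

__all__ = ["ParamGrads", "rollout_tape", "backprop_rollout", "euclidean_grad"]


@dataclass
class ParamGrads:
    """Gradient container mirroring (W2, W1, v)."""

    W2: np.ndarray
    W1: np.ndarray
    v: np.ndarray

    @classmethod
    def zeros_like(cls, theta: NCAParameters) -> "ParamGrads":
        return cls(np.zeros_like(theta.W2), np.zeros_like(theta.W1), np.zeros_like(theta.v))

    def __iadd__(self, other: "ParamGrads") -> "ParamGrads":
        self.W2 += other.W2
        self.W1 += other.W1
        self.v += other.v
        return self

    def scaled(self, a: float) -> "ParamGrads":
        return ParamGrads(self.W2 * a, self.W1 * a, self.v * a)

    def global_norm(self) -> float:
        return float(
            np.sqrt(
                np.sum(self.W2**2) + np.sum(self.W1**2) + np.sum(self.v**2)
            )
        )

    def allfinite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.W2))
            and np.all(np.isfinite(self.W1))
            and np.all(np.isfinite(self.v))
        )


def _forward_step(x, theta, kernels, boundary, mask):
    z = perceive_array(x, kernels, boundary)
    zf = z.reshape(*z.shape[:-2], theta.C * theta.K)
    pre = zf @ theta.W2.T
    act, _ = ACTIVATIONS[theta.activation]
    h = act(pre)
    f = h @ theta.W1.T + theta.v
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite NCA increment during differentiable rollout")
    x1 = enforce_boundary(x + (mask if mask is not None else 1.0) * f, boundary)
    return x1, (zf, pre, h, mask)


def rollout_tape(
    x0: np.ndarray,
    theta: NCAParameters,
    kernels: KernelSet,
    boundary: str,
    t: int,
    masks: list | None = None,
):
    """Run ``t`` update steps from a raw ``(..., S, S, C)`` array, recording a tape.

    ``masks`` is either ``None`` (deterministic, p = 0) or a length-``t`` list
    of gate fields broadcastable to the state shape.
    """
    x = np.asarray(x0, dtype=float)
    tapes = []
    for n in range(t):
        mask = None if masks is None else masks[n]
        x, tape = _forward_step(x, theta, kernels, boundary, mask)
        tapes.append(tape)
    return x, tapes


def backprop_rollout(
    g_final: np.ndarray,
    tapes: list,
    theta: NCAParameters,
    kernels: KernelSet,
    boundary: str,
):
    """Pull ``dL/dx_final`` back through the taped rollout.

    Returns ``(g_x0, ParamGrads)`` summed over any leading batch axes.
    """
    _, act_grad = ACTIVATIONS[theta.activation]
    grads = ParamGrads.zeros_like(theta)
    g = np.asarray(g_final, dtype=float)
    C, K, H = theta.C, theta.K, theta.H
    for zf, pre, h, mask in reversed(tapes):
        # the post-step ring zeroing projects gradients off the ring too
        g = enforce_boundary(g, boundary)
        gf = g if mask is None else mask * g
        gf2 = gf.reshape(-1, C)
        h2 = h.reshape(-1, H)
        grads.W1 += gf2.T @ h2
        grads.v += gf2.sum(axis=0)
        gpre = (gf @ theta.W1) * act_grad(pre)
        grads.W2 += gpre.reshape(-1, H).T @ zf.reshape(-1, C * K)
        gzf = gpre @ theta.W2
        g = g + perceive_adjoint(
            gzf.reshape(*gzf.shape[:-1], C, K), kernels, boundary
        )
    return g, grads


def euclidean_grad(x: np.ndarray, y: np.ndarray, C_obs: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair Euclidean losses and ``dL/dx`` for batched final states.

    ``x`` has shape ``(..., S, S, C)``; ``y`` has shape ``(..., S, S, C_obs)``.
    The loss is the Euclidean norm over observable channels, one scalar per
    leading-index pair; the gradient is zero on hidden channels.
    """
    d = x[..., :C_obs] - y
    sq = np.sum(d * d, axis=(-3, -2, -1))
    L = np.sqrt(sq)
    g = np.zeros_like(x)
    safe = np.where(L > 0, L, 1.0)
    g[..., :C_obs] = d / safe[..., None, None, None]
    return L, g
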