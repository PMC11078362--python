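"""Stability analyses of trained NCA: local perturbation maps, the kappa
adversarial objective, and symmetry-perturbation evaluation.

The adversarial functional for an initial perturbation ``e`` of state ``x0``
after ``n`` deterministic steps is::

    kappa_n(x0, e) = ||e|| - ||Phi^n(x0 + e) - Phi^n(x0)||

Maximising kappa finds the largest perturbation the dynamics forgets;
minimising it finds the smallest perturbation that destroys the future
state.  Rollouts inside kappa are deterministic (p = 0) or share a frozen
mask stream, so the two trajectories remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._backprop import backprop_rollout, rollout_tape
from .core import LatticeState, NCAParameters, UpdateConfig, sample_mask
from .kernels import KernelSet
from .losses import euclidean_loss

__all__ = [
    "PerturbationResult",
    "AdversarialResult",
    "kappa",
    "adversarial_search",
    "local_perturbation_map",
    "symmetry_eval",
    "SYMMETRY_TRANSFORMS",
]


def _frozen_masks(x0: LatticeState, cfg: UpdateConfig | None, n: int):
    """One mask stream shared by both rollouts; ``None`` when deterministic."""
    if cfg is None or cfg.p == 0.0:
        return None
    rng = np.random.default_rng(cfg.seed)
    return [sample_mask(x0.S, x0.C, cfg, rng) for _ in range(n)]


def _final(values, theta, kernels, boundary, n, masks):
    x, _ = rollout_tape(values, theta, kernels, boundary, n, masks)
    return x


def kappa(
    theta: NCAParameters,
    x0: LatticeState,
    e: np.ndarray,
    n: int,
    kernels: KernelSet,
    cfg: UpdateConfig | None = None,
) -> float:
    """Evaluate ``||e|| - ||Phi^n(x0 + e) - Phi^n(x0)||`` (Euclidean norms)."""
    e = np.asarray(e, dtype=float)
    if e.shape != x0.values.shape:
        raise ValueError(f"perturbation shape {e.shape} != state shape {x0.values.shape}")
    masks = _frozen_masks(x0, cfg, n)
    base = _final(x0.values, theta, kernels, x0.boundary, n, masks)
    pert = _final(x0.values + e, theta, kernels, x0.boundary, n, masks)
    return float(np.linalg.norm(e) - np.linalg.norm(pert - base))


@dataclass
class AdversarialResult:
    """Outcome of a kappa optimisation."""

    perturbation: np.ndarray
    kappa: float
    mode: str
    trace: list[float] = field(default_factory=list)


def _kappa_and_grad(theta, x0, e, n, kernels, masks, base):
    """kappa value and its gradient with respect to the perturbation field."""
    pert, tapes = rollout_tape(x0.values + e, theta, kernels, x0.boundary, n, masks)
    diff = pert - base
    dn = float(np.linalg.norm(diff))
    en = float(np.linalg.norm(e))
    g = np.zeros_like(e)
    if en > 0:
        g += e / en
    if dn > 0:
        g_final = diff / dn
        g_in, _ = backprop_rollout(g_final, tapes, theta, kernels, x0.boundary)
        g -= g_in
    return en - dn, g


def adversarial_search(
    theta: NCAParameters,
    x0: LatticeState,
    n: int,
    kernels: KernelSet,
    mode: str = "minimise",
    iterations: int = 200,
    step_size: float = 0.1,
    init_norm: float = 1e-2,
    cfg: UpdateConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> AdversarialResult:
    """Gradient search on kappa with a fixed step and backtracking acceptance.

    ``maximise`` seeks a large perturbation whose effect the rollout forgets;
    ``minimise`` a small perturbation that wrecks the final state.  The start
    point is uniform noise scaled to norm ``init_norm``; a proposed gradient
    step is only accepted if it improves the objective (halving the step on
    rejection), so the recorded trace is monotone.
    """
    if mode not in ("maximise", "minimise"):
        raise ValueError("mode must be 'maximise' or 'minimise'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sign = 1.0 if mode == "maximise" else -1.0
    masks = _frozen_masks(x0, cfg, n)
    base = _final(x0.values, theta, kernels, x0.boundary, n, masks)

    e = rng.uniform(-1.0, 1.0, size=x0.values.shape)
    e *= init_norm / np.linalg.norm(e)
    best_k, g = _kappa_and_grad(theta, x0, e, n, kernels, masks, base)
    trace = [best_k]
    lr = step_size
    for _ in range(iterations):
        prop = e + sign * lr * g
        k_prop, g_prop = _kappa_and_grad(theta, x0, prop, n, kernels, masks, base)
        if not np.isfinite(k_prop):
            raise FloatingPointError("non-finite adversarial objective")
        if sign * k_prop > sign * best_k:
            e, best_k, g = prop, k_prop, g_prop
            lr = min(lr * 1.2, step_size * 10)
        else:
            lr *= 0.5
            if lr < 1e-8:
                break
        trace.append(best_k)
    return AdversarialResult(perturbation=e, kappa=best_k, mode=mode, trace=trace)


@dataclass
class PerturbationResult:
    """Heatmap of final-state sensitivity to single-pixel perturbations."""

    heatmap: np.ndarray
    threshold: float
    n: int
    snapshots: dict = field(default_factory=dict)


def local_perturbation_map(
    theta: NCAParameters,
    x0: LatticeState,
    n: int,
    kernels: KernelSet,
    magnitude: float = 1.0,
    threshold: float = 0.1,
    cfg: UpdateConfig | None = None,
    snapshot_sites: list | None = None,
    batch: int = 64,
) -> PerturbationResult:
    """For each lattice site, perturb that pixel in ``x0``, roll out ``n``
    steps and count final-state pixels whose observable-channel max change
    exceeds ``threshold``.

    The perturbation adds ``magnitude`` to every observable channel of the
    site.  With a frozen mask stream (or p = 0) the map is deterministic.
    """
    if magnitude <= threshold:
        raise ValueError("perturbation magnitude must exceed the change threshold")
    S, C, C_obs = x0.S, x0.C, x0.C_obs
    masks = _frozen_masks(x0, cfg, n)
    base = _final(x0.values, theta, kernels, x0.boundary, n, masks)
    heat = np.zeros((S, S), dtype=int)
    snapshots: dict = {}
    sites = [(i, j) for i in range(S) for j in range(S)]
    for start in range(0, len(sites), batch):
        chunk = sites[start : start + batch]
        xs = np.repeat(x0.values[None], len(chunk), axis=0)
        for b, (i, j) in enumerate(chunk):
            xs[b, i, j, :C_obs] += magnitude
        bm = None if masks is None else [np.repeat(m[None], len(chunk), axis=0) for m in masks]
        finals = _final(xs, theta, kernels, x0.boundary, n, bm)
        change = np.abs(finals[..., :C_obs] - base[..., :C_obs]).max(axis=-1)
        counts = (change > threshold).sum(axis=(1, 2))
        for b, (i, j) in enumerate(chunk):
            heat[i, j] = counts[b]
            if snapshot_sites and (i, j) in snapshot_sites:
                snapshots[(i, j)] = finals[b].copy()
    return PerturbationResult(heatmap=heat, threshold=threshold, n=n, snapshots=snapshots)


def _rot45(values: np.ndarray) -> np.ndarray:
    return ndimage.rotate(
        values, 45.0, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
    )


SYMMETRY_TRANSFORMS = {
    "identity": lambda v: v,
    "rot90": lambda v: np.rot90(v, 1, axes=(0, 1)).copy(),
    "rot180": lambda v: np.rot90(v, 2, axes=(0, 1)).copy(),
    "rot270": lambda v: np.rot90(v, 3, axes=(0, 1)).copy(),
    "rot45": _rot45,
    "flip_h": lambda v: v[:, ::-1].copy(),
    "flip_v": lambda v: v[::-1].copy(),
}


def symmetry_eval(
    theta: NCAParameters,
    x0: LatticeState,
    target: np.ndarray,
    n: int,
    kernels: KernelSet,
    transforms: list[str] = ("identity", "rot90", "rot180", "rot270", "flip_h", "flip_v"),
    cfg: UpdateConfig | None = None,
) -> dict[str, float]:
    """Per-transform losses: roll out from ``T(x0)`` and compare to ``T(target)``.

    ``target`` holds the expected observable channels of the final state.  A
    rotation-equivariant rule scores identically across on-lattice
    transforms; asymmetric-kernel rules typically degrade under them.
    """
    results: dict[str, float] = {}
    for name in transforms:
        if name not in SYMMETRY_TRANSFORMS:
            raise ValueError(f"unknown transform {name!r}")
        T = SYMMETRY_TRANSFORMS[name]
        xt = T(x0.values)
        masks = _frozen_masks(x0, cfg, n)
        final = _final(xt, theta, kernels, x0.boundary, n, masks)
        results[name] = euclidean_loss(
            final[..., : x0.C_obs], T(np.asarray(target, dtype=float))
        )
    return results
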