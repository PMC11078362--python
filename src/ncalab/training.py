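"""Training NCA by transition-wise backpropagation through time.

A data trajectory ``y[m, r]`` (time index ``m = 0..M``, trajectory copy
``r = 0..R-1``) is learned as a set of transitions ``x[m-1, r] -> x[m, r]``,
each spanning ``t`` NCA steps.  Every epoch the (time x copy) grid is
shuffled into mini-batch chunks; per-chunk loss gradients are accumulated,
normalised to unit global L2 norm, and applied in one Nesterov-Adam (Nadam)
update.  Predicted intermediate states are propagated between epochs for all
trajectory copies except one, which is re-initialised to the data — a form
of data augmentation that balances fast early learning against long-horizon
consistency of the hidden channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._backprop import ParamGrads, backprop_rollout, euclidean_grad, rollout_tape
from .core import NCAParameters, UpdateConfig, sample_mask
from .kernels import KernelSet
from .losses import LossSpec

__all__ = [
    "TrainingData",
    "TrainingConfig",
    "NadamState",
    "train",
    "normalise_gradient",
    "optimiser_update",
    "transition_gradients",
    "gradient_check",
]


@dataclass
class TrainingData:
    """Observed states ``y`` with shape ``(M+1, R, S, S, C_obs)`` and step ratio ``t``.

    NCA step ``n`` aligns with data frame ``m`` at ``n = m * t``.
    """

    y: np.ndarray
    t: int
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 5:
            raise ValueError(f"data must be (M+1, R, S, S, C_obs), got shape {y.shape}")
        if y.shape[0] < 2:
            raise ValueError("need at least M = 1 transition")
        if self.t < 1:
            raise ValueError("steps per data interval t must be >= 1")
        if not np.all(np.isfinite(y)):
            raise ValueError("training data contains non-finite values")
        self.y = y

    @property
    def M(self) -> int:
        return self.y.shape[0] - 1

    @property
    def R(self) -> int:
        return self.y.shape[1]

    @property
    def S(self) -> int:
        return self.y.shape[2]

    @property
    def C_obs(self) -> int:
        return self.y.shape[4]


@dataclass
class TrainingConfig:
    """Optimisation settings.

    ``B`` mini-batch chunks per epoch (recommended ``10 < M*R/B < 100``);
    ``reinit_batch`` is the trajectory copy reset to data each epoch, all
    others propagate their predicted states.
    """

    epochs: int = 300
    B: int = 1
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    reinit_batch: int = 0
    warmup_reinit_epochs: int = 0
    select: str = "best"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.B < 1:
            raise ValueError("mini-batch count B must be >= 1")
        if self.select not in ("best", "final"):
            raise ValueError("select must be 'best' or 'final'")


@dataclass
class NadamState:
    """First/second moment accumulators for the Nadam optimiser."""

    m: ParamGrads
    n: ParamGrads
    step: int = 0

    @classmethod
    def zeros_like(cls, theta: NCAParameters) -> "NadamState":
        return cls(ParamGrads.zeros_like(theta), ParamGrads.zeros_like(theta))


def normalise_gradient(grads: ParamGrads, eps: float = 1e-12) -> ParamGrads:
    """Scale the gradient to unit global L2 norm; zero gradients pass through."""
    if not grads.allfinite():
        raise FloatingPointError("non-finite gradient")
    norm = grads.global_norm()
    if norm < eps:
        return grads
    return grads.scaled(1.0 / norm)


def optimiser_update(
    theta: NCAParameters,
    grads: ParamGrads,
    state: NadamState,
    cfg: TrainingConfig,
) -> NCAParameters:
    """One Nadam step (Adam with Nesterov momentum); mutates ``state``, returns new params.

    With bias-corrected moments ``m^`` and ``n^`` at step ``i``::

        theta <- theta - lr * (b1*m^ + (1-b1)*g/(1-b1^i)) / (sqrt(n^) + eps)
    """
    state.step += 1
    i = state.step
    b1, b2 = cfg.beta1, cfg.beta2
    out = theta.copy()
    for name in ("W2", "W1", "v"):
        g = getattr(grads, name)
        m = getattr(state.m, name)
        n = getattr(state.n, name)
        m[...] = b1 * m + (1 - b1) * g
        n[...] = b2 * n + (1 - b2) * g**2
        m_hat = m / (1 - b1**i)
        n_hat = n / (1 - b2**i)
        update = cfg.lr * (b1 * m_hat + (1 - b1) * g / (1 - b1**i)) / (
            np.sqrt(n_hat) + cfg.eps
        )
        getattr(out, name)[...] = getattr(theta, name) - update
    return out


def _sample_step_masks(update_cfg, n_pairs, S, C, t, rng):
    if update_cfg is None or update_cfg.p == 0.0:
        return None
    return [
        sample_mask(S, C, update_cfg, rng, lead=(n_pairs,)) for _ in range(t)
    ]


def transition_gradients(
    theta: NCAParameters,
    x_prev: np.ndarray,
    y_target: np.ndarray,
    t: int,
    kernels: KernelSet,
    boundary: str,
    masks: list | None = None,
    scale: float = 1.0,
):
    """Losses and parameter gradients for a batch of transitions.

    ``x_prev``: ``(P, S, S, C)`` starting states; ``y_target``: ``(P, S, S,
    C_obs)``.  Returns per-pair Euclidean losses, the gradient of
    ``scale * sum(losses)``, and the predicted end states.
    """
    C_obs = y_target.shape[-1]
    x_hat, tapes = rollout_tape(x_prev, theta, kernels, boundary, t, masks)
    losses, g_final = euclidean_grad(x_hat, y_target, C_obs)
    _, grads = backprop_rollout(g_final * scale, tapes, theta, kernels, boundary)
    return losses, grads, x_hat


def _chunks(perm: np.ndarray, B: int) -> list[np.ndarray]:
    return [c for c in np.array_split(perm, B)]


def train(
    theta: NCAParameters,
    data: TrainingData,
    cfg: TrainingConfig,
    kernels: KernelSet,
    loss: LossSpec | None = None,
    update_cfg: UpdateConfig | None = None,
):
    """Fit NCA parameters to a trajectory batch; returns ``(theta*, loss history)``.

    ``theta*`` is the parameter snapshot at the epoch with minimal recorded
    training loss.  The input data array is never mutated.
    """
    loss = loss or LossSpec()
    if kernels.K != theta.K:
        raise ValueError("kernel bank size does not match parameters")
    if loss.kind != "euclidean":
        raise NotImplementedError(
            "training differentiates the euclidean loss only; "
            f"{loss.kind!r} losses are available for evaluation"
        )
    if theta.C < data.C_obs:
        raise ValueError(f"model C={theta.C} smaller than data C_obs={data.C_obs}")
    if not 0 <= cfg.reinit_batch < data.R:
        raise ValueError("reinit_batch out of range")
    M, R, S, C_obs = data.M, data.R, data.S, data.C_obs
    C = theta.C
    rng = np.random.default_rng(cfg.seed)

    # stored predicted states: observable channels start at the data, hidden at zero
    X = np.zeros((M + 1, R, S, S, C))
    X[..., :C_obs] = data.y

    history: list[float] = []
    best_loss = np.inf
    best_theta = theta.copy()
    opt = NadamState.zeros_like(theta)

    for epoch in range(cfg.epochs):
        ms_chunks = _chunks(rng.permutation(np.arange(1, M + 1)), cfg.B)
        rs_chunks = _chunks(rng.permutation(np.arange(R)), cfg.B)
        grad_acc = ParamGrads.zeros_like(theta)
        epoch_losses: list[float] = []
        stash: list[tuple[int, int, np.ndarray]] = []
        for b, (ms, rs) in enumerate(zip(ms_chunks, rs_chunks)):
            if ms.size == 0 or rs.size == 0:
                continue
            pairs = [(m, r) for m in ms for r in rs]
            x_prev = np.stack([X[m - 1, r] for m, r in pairs])
            y_t = np.stack([data.y[m, r] for m, r in pairs])
            masks = _sample_step_masks(update_cfg, len(pairs), S, C, data.t, rng)
            try:
                losses, grads, x_hat = transition_gradients(
                    theta, x_prev, y_t, data.t, kernels=kernels,
                    boundary=data.boundary, masks=masks, scale=1.0 / (M * R),
                )
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, chunk {b}: {exc}"
                ) from None
            if not (np.all(np.isfinite(losses)) and grads.allfinite()):
                raise RuntimeError(
                    f"non-finite loss or gradient at epoch {epoch}, chunk {b}"
                )
            grad_acc += grads
            epoch_losses.extend(float(v) for v in losses)
            for (m, r), xh in zip(pairs, x_hat):
                stash.append((m, r, xh))
        epoch_loss = float(np.mean(epoch_losses))
        history.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_theta = theta.copy()
        theta = optimiser_update(theta, normalise_gradient(grad_acc), opt, cfg)
        # propagate predictions; re-initialise exactly one trajectory copy.
        # during warmup every copy is re-initialised (fast early learning);
        # afterwards only `reinit_batch` is, and the rest carry their
        # predicted (hidden-channel-bearing) states forward between epochs.
        if epoch < cfg.warmup_reinit_epochs:
            X[..., :C_obs] = data.y
            X[..., C_obs:] = 0.0
        else:
            for m, r, xh in stash:
                if r != cfg.reinit_batch:
                    X[m, r] = xh
            X[:, cfg.reinit_batch] = 0.0
            X[:, cfg.reinit_batch, ..., :C_obs] = data.y[:, cfg.reinit_batch]
    if cfg.select == "final":
        return theta, history
    return best_theta, history


def gradient_check(
    theta: NCAParameters,
    x_prev: np.ndarray,
    y_target: np.ndarray,
    t: int,
    kernels: KernelSet,
    boundary: str = "periodic",
    masks: list | None = None,
    n_params: int = 60,
    fd_eps: float = 1e-5,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Max relative error of the analytic BPTT gradient vs central finite differences.

    Evaluated on a random subset of parameters of a small instance; masks (if
    any) are held fixed across all evaluations so the objective is smooth.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    C_obs = y_target.shape[-1]

    def loss_of(th: NCAParameters) -> float:
        x_hat, _ = rollout_tape(x_prev, th, kernels, boundary, t, masks)
        L, _ = euclidean_grad(x_hat, y_target, C_obs)
        return float(np.sum(L))

    _, grads, _ = transition_gradients(
        theta, x_prev, y_target, t, kernels, boundary, masks=masks
    )
    flat_specs = []
    for name in ("W2", "W1", "v"):
        arr = getattr(theta, name)
        for idx in range(arr.size):
            flat_specs.append((name, idx))
    take = min(n_params, len(flat_specs))
    sel = rng.choice(len(flat_specs), size=take, replace=False)
    max_rel = 0.0
    for s in sel:
        name, idx = flat_specs[s]
        th = theta.copy()
        arr = getattr(th, name)
        orig = arr.flat[idx]
        arr.flat[idx] = orig + fd_eps
        lp = loss_of(th)
        arr.flat[idx] = orig - fd_eps
        lm = loss_of(th)
        arr.flat[idx] = orig
        fd = (lp - lm) / (2 * fd_eps)
        an = getattr(grads, name).flat[idx]
        denom = max(abs(fd), abs(an), 1e-6)
        max_rel = max(max_rel, abs(fd - an) / denom)
    return max_rel
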