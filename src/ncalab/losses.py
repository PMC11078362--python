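"""Distances between lattice states, evaluated on observable channels only.

The Euclidean norm is the workhorse (and the training default); probability-
mass distances (Hellinger, Bhattacharyya) and a Fourier-magnitude distance
are provided as alternatives for pattern-matching evaluation.  Hidden
channels are never penalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import LatticeState

__all__ = [
    "LossSpec",
    "euclidean_loss",
    "mass_based_loss",
    "spectral_loss",
    "aggregate_loss",
    "evaluate_loss",
]

LOSS_KINDS = ("euclidean", "hellinger", "bhattacharyya", "spectral")


@dataclass(frozen=True)
class LossSpec:
    """Choice of state distance; always restricted to observable channels."""

    kind: str = "euclidean"
    observable_only: bool = True

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"loss kind must be one of {LOSS_KINDS}")


def _observables(x, y, C_obs: int | None):
    xv = x.values if isinstance(x, LatticeState) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, LatticeState) else np.asarray(y, dtype=float)
    if C_obs is None:
        cx = x.C_obs if isinstance(x, LatticeState) else xv.shape[-1]
        cy = y.C_obs if isinstance(y, LatticeState) else yv.shape[-1]
        C_obs = min(cx, cy)
    xv, yv = xv[..., :C_obs], yv[..., :C_obs]
    if xv.shape != yv.shape:
        raise ValueError(f"observable shapes differ: {xv.shape} vs {yv.shape}")
    return xv, yv


def euclidean_loss(x, y, C_obs: int | None = None) -> float:
    """Euclidean norm ``sqrt(sum (x_ijc - y_ijc)^2)`` over observable channels."""
    xv, yv = _observables(x, y, C_obs)
    return float(np.sqrt(np.sum((xv - yv) ** 2)))


def _to_mass(field: np.ndarray) -> np.ndarray:
    # shift each channel to be nonnegative, then normalise to unit mass
    shifted = field - field.min() + 1e-9
    total = shifted.sum()
    if total <= 0:
        raise ValueError("all-zero mass after normalisation")
    return shifted / total


def mass_based_loss(x, y, kind: str = "hellinger", C_obs: int | None = None) -> float:
    """Hellinger or Bhattacharyya distance on per-channel normalised masses.

    Each observable channel is shifted by its minimum (plus a tiny floor) and
    normalised to sum one, so real-valued states are admissible; the textbook
    distance is then averaged over channels.
    """
    if kind not in ("hellinger", "bhattacharyya"):
        raise ValueError("kind must be 'hellinger' or 'bhattacharyya'")
    xv, yv = _observables(x, y, C_obs)
    vals = []
    for c in range(xv.shape[-1]):
        p = _to_mass(xv[..., c])
        q = _to_mass(yv[..., c])
        bc = float(np.sum(np.sqrt(p * q)))
        bc = min(bc, 1.0)  # clip float excess above 1
        if kind == "hellinger":
            vals.append(np.sqrt(1.0 - bc))
        else:
            vals.append(-np.log(max(bc, 1e-300)))
    return float(np.mean(vals))


def spectral_loss(x, y, C_obs: int | None = None) -> float:
    """Euclidean distance between 2-D Fourier magnitude spectra, summed over channels.

    Magnitude (not complex) spectra are compared, so the distance is invariant
    to cyclic shifts of either input.
    """
    xv, yv = _observables(x, y, C_obs)
    total = 0.0
    for c in range(xv.shape[-1]):
        mx = np.abs(np.fft.fft2(xv[..., c]))
        my = np.abs(np.fft.fft2(yv[..., c]))
        total += float(np.sqrt(np.sum((mx - my) ** 2)))
    return total


def evaluate_loss(x, y, spec: LossSpec, C_obs: int | None = None) -> float:
    """Dispatch on a :class:`LossSpec`."""
    if spec.kind == "euclidean":
        return euclidean_loss(x, y, C_obs)
    if spec.kind in ("hellinger", "bhattacharyya"):
        return mass_based_loss(x, y, spec.kind, C_obs)
    return spectral_loss(x, y, C_obs)


def aggregate_loss(losses: Iterable[float]) -> float:
    """Unweighted arithmetic mean over all compared (time, batch) pairs."""
    vals = np.asarray(list(losses), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot aggregate an empty set of losses")
    return float(vals.mean())
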