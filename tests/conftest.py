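"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ncalab import init_parameters, standard_kernels
from ncalab.kernels import KERNEL_MATRICES


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def id_lap_kernels():
    return standard_kernels(["identity", "laplacian"])


@pytest.fixture
def full_kernels():
    return standard_kernels(
        ["identity", "average", "gradient_x", "gradient_y", "laplacian"]
    )


def brute_force_correlate(field: np.ndarray, kernel: np.ndarray, boundary: str) -> np.ndarray:
    """Direct double-sum 3x3 cross-correlation; the convolution oracle."""
    S1, S2 = field.shape
    out = np.zeros_like(field, dtype=float)
    for i in range(S1):
        for j in range(S2):
            acc = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if boundary == "periodic":
                        acc += kernel[di + 1, dj + 1] * field[ii % S1, jj % S2]
                    elif 0 <= ii < S1 and 0 <= jj < S2:
                        acc += kernel[di + 1, dj + 1] * field[ii, jj]
            out[i, j] = acc
    return out


def diffusion_parameters(d: float = 0.2, extra_hidden: int = 0):
    """Hand-built weights realising f = d * laplacian(x) on channel 0.

    Assumes the kernel bank (identity, laplacian) so perception index 1 is
    the Laplacian response; linear activation makes the step one explicit
    Euler heat-equation update.
    """
    from ncalab import NCAParameters

    C = 1 + extra_hidden
    K = 2
    H = 4 * C
    W2 = np.zeros((H, C * K))
    W2[0, 1] = 1.0  # hidden unit 0 reads the laplacian of channel 0
    W1 = np.zeros((C, H))
    W1[0, 0] = d
    return NCAParameters(W2=W2, W1=W1, v=np.zeros(C), activation="linear")


def euler_heat_trajectory(x0: np.ndarray, d: float, steps: int) -> list[np.ndarray]:
    """Explicit-Euler diffusion with the nine-point Laplacian; brute-force oracle."""
    lap = KERNEL_MATRICES["laplacian"]
    traj = [x0.copy()]
    for _ in range(steps):
        prev = traj[-1]
        traj.append(prev + d * brute_force_correlate(prev, lap, "periodic"))
    return traj


@pytest.fixture
def random_theta(rng):
    """Small random parameters with nonzero output layer (nontrivial dynamics)."""
    theta = init_parameters(C=2, K=2, rng=rng)
    theta.W1 = rng.normal(0.0, 0.3, theta.W1.shape)
    theta.v = rng.normal(0.0, 0.05, theta.v.shape)
    return theta
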