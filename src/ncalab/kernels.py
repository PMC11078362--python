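"""Fixed 3x3 perception kernels.

The NCA never learns its spatial operators: perception is built from a small
bank of hard-coded 3x3 kernels that discretise differential operators
(identity, local average, Sobel gradients, nine-point Laplacian).  Because a
3x3 kernel only sees the Moore neighbourhood, at most 9 linearly independent
kernels exist; the bank below is the standard interpretable subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Kernel", "KernelSet", "standard_kernels", "KERNEL_MATRICES"]

# Row index i increases downwards (y), column index j increases rightwards (x).
# Kernels are applied as cross-correlations in these coordinates.
KERNEL_MATRICES: dict[str, np.ndarray] = {
    "identity": np.array(
        [[0.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]]
    ),
    "average": np.full((3, 3), 1.0 / 9.0),
    "gradient_x": np.array(
        [[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]]
    )
    / 8.0,
    "gradient_y": np.array(
        [[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]]
    )
    / 8.0,
    "laplacian": np.array(
        [[1.0, 2.0, 1.0], [2.0, -12.0, 2.0], [1.0, 2.0, 1.0]]
    )
    / 4.0,
}


@dataclass(frozen=True)
class Kernel:
    """A named 3x3 convolution kernel."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"kernel {self.name!r} must be 3x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class KernelSet:
    """An ordered bank of kernels; order fixes the perception-channel layout."""

    kernels: tuple[Kernel, ...]
    names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.kernels) <= 9:
            raise ValueError("a kernel set holds between 1 and 9 kernels")
        stacked = np.stack([k.matrix.ravel() for k in self.kernels])
        if np.linalg.matrix_rank(stacked) != len(self.kernels):
            raise ValueError("kernel matrices must be linearly independent")
        object.__setattr__(self, "names", tuple(k.name for k in self.kernels))

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def K(self) -> int:
        return len(self.kernels)

    def stacked(self) -> np.ndarray:
        """All kernel matrices as a (K, 3, 3) array."""
        return np.stack([k.matrix for k in self.kernels])


def standard_kernels(names: list[str] | tuple[str, ...]) -> KernelSet:
    """Build a :class:`KernelSet` from the named standard kernels.

    Parameters
    ----------
    names
        Non-empty sequence drawn without repetition from ``identity``,
        ``average``, ``gradient_x``, ``gradient_y``, ``laplacian``.
    """
    if not names:
        raise ValueError("at least one kernel name is required")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate kernel names in {list(names)!r}")
    kernels = []
    for name in names:
        if name not in KERNEL_MATRICES:
            raise KeyError(
                f"unknown kernel {name!r}; choose from {sorted(KERNEL_MATRICES)}"
            )
        kernels.append(Kernel(name, KERNEL_MATRICES[name].copy()))
    return KernelSet(tuple(kernels))
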