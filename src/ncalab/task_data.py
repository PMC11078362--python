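"""Training-data generators: Gray-Scott trajectories, noise corruption, and
the image-morphing task.

The Gray-Scott system models two species with cubic autocatalysis
``A + 2B -> 3B``: A is fed towards density 1 at rate ``alpha`` while B is
removed at rate ``gamma + alpha``::

    dA/dt = D_A lap(A) - A B^2 + alpha (1 - A)
    dB/dt = D_B lap(B) + A B^2 - (gamma + alpha) B

solved by explicit Euler on a periodic lattice.  The Laplacian here is the
same nine-point kernel the NCA perceives with, so the learned rule and the
ground-truth discretisation share one spatial operator.

The morphing task turns a short RGBA image sequence into trajectory data:
frames are downsampled, embedded in a zero-padded lattice (fixed-zero
boundary), the final frame is repeated so the end state is trained as an
attractor, and copies are randomly shifted and lightly noised — without that
noise the final self-transition has divergent gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kernels import KERNEL_MATRICES
from .training import TrainingData

__all__ = [
    "GrayScottParams",
    "NoiseSpec",
    "MorphTaskSpec",
    "gray_scott_rhs",
    "simulate_gray_scott",
    "make_initial_condition",
    "corrupt_with_noise",
    "make_morph_sequence",
    "synthetic_shapes",
    "rotate_trajectory",
]

_LAP = KERNEL_MATRICES["laplacian"]


@dataclass
class GrayScottParams:
    """Gray-Scott rates and discretisation settings (maze-pattern defaults)."""

    D_A: float = 0.1
    D_B: float = 0.05
    alpha: float = 0.06230
    gamma: float = 0.06268
    dt: float = 1.0
    S: int = 64
    steps: int = 1024
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if min(self.D_A, self.D_B, self.alpha, self.gamma) < 0:
            raise ValueError("all rates must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        # explicit-Euler diffusion stability: the nine-point Laplacian has
        # spectral radius 6 at the centre weight -3, so require dt*D < 1/3
        dmax = max(self.D_A, self.D_B)
        if self.dt * dmax >= 1.0 / 3.0:
            raise ValueError(
                f"dt*D = {self.dt * dmax:.3f} violates the explicit-scheme "
                "stability heuristic dt*D < 1/3"
            )
        if self.boundary != "periodic":
            raise ValueError("the PDE solver is periodic-only")


def _laplacian(f: np.ndarray) -> np.ndarray:
    return ndimage.correlate(f, _LAP, mode="wrap")


def gray_scott_rhs(A: np.ndarray, B: np.ndarray, params: GrayScottParams):
    """Elementwise right-hand sides ``(dA/dt, dB/dt)`` on periodic fields."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError(f"A and B must be matching 2-D fields, got {A.shape}, {B.shape}")
    AB2 = A * B * B
    dA = params.D_A * _laplacian(A) - AB2 + params.alpha * (1.0 - A)
    dB = params.D_B * _laplacian(B) + AB2 - (params.gamma + params.alpha) * B
    return dA, dB


def simulate_gray_scott(
    A0: np.ndarray,
    B0: np.ndarray,
    params: GrayScottParams,
    sample_every: int = 1,
) -> TrainingData:
    """Explicit-Euler integration; states sampled every ``sample_every`` steps.

    Returns :class:`TrainingData` with two observable channels (A, B) and a
    single trajectory copy, shape ``(M+1, 1, S, S, 2)`` with
    ``M = steps // sample_every``.
    """
    if sample_every < 1 or params.steps % sample_every != 0:
        raise ValueError("sample_every must be >= 1 and divide the step count")
    A = np.asarray(A0, dtype=float).copy()
    B = np.asarray(B0, dtype=float).copy()
    frames = [np.stack([A, B], axis=-1)]
    for n in range(params.steps):
        dA, dB = gray_scott_rhs(A, B, params)
        A = A + params.dt * dA
        B = B + params.dt * dB
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
            raise FloatingPointError(f"Gray-Scott simulation blew up at step {n + 1}")
        if (n + 1) % sample_every == 0:
            frames.append(np.stack([A, B], axis=-1))
    y = np.stack(frames)[:, None]  # (M+1, R=1, S, S, 2)
    return TrainingData(y=y, t=sample_every, boundary=params.boundary)


def make_initial_condition(
    kind: str, S: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded initial fields ``(A, B)`` for the Gray-Scott system.

    ``blobs``: A = 1 background with a few rectangular B patches;
    ``squares``: one large central B square; ``high_frequency``: blobs plus
    checkerboard/noise patches carrying power well above half-Nyquist, for
    generalisation tests on inputs never seen in training.
    """
    rng = np.random.default_rng(seed)
    A = np.ones((S, S))
    B = np.zeros((S, S))
    if kind == "blobs":
        for _ in range(rng.integers(3, 6)):
            h = int(rng.integers(S // 16 + 1, S // 6 + 2))
            w = int(rng.integers(S // 16 + 1, S // 6 + 2))
            i = int(rng.integers(0, S - h))
            j = int(rng.integers(0, S - w))
            B[i : i + h, j : j + w] = 1.0
            A[i : i + h, j : j + w] = 0.5
    elif kind == "squares":
        q = S // 4
        B[q : 3 * q, q : 3 * q] = 1.0
        A[q : 3 * q, q : 3 * q] = 0.5
    elif kind == "high_frequency":
        A, B = make_initial_condition("blobs", S, seed)
        cb = np.indices((S, S)).sum(axis=0) % 2  # checkerboard: pure Nyquist mode
        for _ in range(3):
            h = int(rng.integers(S // 8, S // 4 + 1))
            i = int(rng.integers(0, S - h))
            j = int(rng.integers(0, S - h))
            B[i : i + h, j : j + h] = cb[i : i + h, j : j + h]
            A[i : i + h, j : j + h] = 0.5 + 0.5 * rng.random((h, h))
    else:
        raise ValueError(f"unknown initial-condition kind {kind!r}")
    return A, B


@dataclass
class NoiseSpec:
    """Measurement-noise intensity ``xi`` in [0, 1] (0 = clean, 1 = pure noise)."""

    xi: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("corruption intensity xi must lie in [0, 1]")


def corrupt_with_noise(
    data: TrainingData, noise: NoiseSpec, rng: np.random.Generator | None = None
) -> TrainingData:
    """Mix each element with uniform noise: ``y~ = (1 - xi) y + xi eta``.

    ``eta ~ U(min y, max y)`` with the extrema taken over the whole
    trajectory.  The input is left unmodified; ``xi = 0`` returns an exact
    copy.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    y = data.y
    if noise.xi == 0.0:
        return TrainingData(y=y.copy(), t=data.t, boundary=data.boundary)
    lo, hi = float(y.min()), float(y.max())
    eta = rng.uniform(lo, hi, size=y.shape)
    return TrainingData(
        y=(1.0 - noise.xi) * y + noise.xi * eta, t=data.t, boundary=data.boundary
    )


# ---------------------------------------------------------------------------
# image morphing task


@dataclass
class MorphTaskSpec:
    """Construction of morphing training data from an RGBA image sequence."""

    images: list = field(default_factory=list)
    resolution: int = 60
    pad: int = 16
    R: int = 4
    shift_max: int = 8
    repeat_final: int = 2
    noise_amplitude: float = 0.005
    t: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("need at least two images to morph between")
        if self.pad < 1:
            raise ValueError("padded lattice must be strictly larger than the image")
        if self.shift_max > self.pad:
            raise ValueError("shift range cannot push content outside the lattice")
        for im in self.images:
            a = np.asarray(im)
            if a.ndim != 3 or a.shape[2] != 4:
                raise ValueError("images must be RGBA (h, w, 4)")
            if a.min() < 0 or a.max() > 1:
                raise ValueError("image values must lie in [0, 1]")


def _downsample(img: np.ndarray, res: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h == w and h % res == 0:
        f = h // res
        return img.reshape(res, f, res, f, 4).mean(axis=(1, 3))
    from skimage.transform import resize

    return resize(img, (res, res, 4), anti_aliasing=True, preserve_range=True)


def make_morph_sequence(
    spec: MorphTaskSpec, rng: np.random.Generator | None = None
) -> TrainingData:
    """Build fixed-boundary morphing data: ``(M+1, R, S, S, 4)`` with
    ``S = resolution + 2*pad`` and ``M = n_images - 1 + (repeat_final - 1)``.

    Each of the ``R`` copies shares one random spatial shift across its
    frames (so a rule cannot key on absolute position), and small uniform
    noise is added to every data frame.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    frames = [_downsample(np.asarray(im, dtype=float), spec.resolution) for im in spec.images]
    frames = frames + [frames[-1]] * (spec.repeat_final - 1)
    S = spec.resolution + 2 * spec.pad
    M = len(frames) - 1
    y = np.zeros((M + 1, spec.R, S, S, 4))
    for r in range(spec.R):
        if r == 0 or spec.shift_max == 0:
            di = dj = 0  # first copy is the centred, unshifted reference
        else:
            di = int(rng.integers(-spec.shift_max, spec.shift_max + 1))
            dj = int(rng.integers(-spec.shift_max, spec.shift_max + 1))
        i0, j0 = spec.pad + di, spec.pad + dj
        for m, fr in enumerate(frames):
            y[m, r, i0 : i0 + spec.resolution, j0 : j0 + spec.resolution] = fr
    if spec.noise_amplitude > 0:
        y = y + rng.uniform(-spec.noise_amplitude, spec.noise_amplitude, size=y.shape)
        # the boundary ring stays exactly zero under fixed-zero dynamics
        y[:, :, 0, :, :] = 0.0
        y[:, :, -1, :, :] = 0.0
        y[:, :, :, 0, :] = 0.0
        y[:, :, :, -1, :] = 0.0
    return TrainingData(y=y, t=spec.t, boundary="fixed-zero")


SHAPE_KINDS = ("disc", "ring", "cross", "star", "glider")


def synthetic_shapes(
    kinds: list[str], size: int = 120, seed: int = 0
) -> list[np.ndarray]:
    """Deterministic licence-free RGBA rasters of simple shapes in [0, 1].

    Alpha is 1 inside the shape and 0 outside; colour channels are zero
    wherever alpha is zero.
    """
    rng = np.random.default_rng(seed)
    ii, jj = np.indices((size, size)).astype(float)
    c = (size - 1) / 2.0
    r = np.hypot(ii - c, jj - c)
    images = []
    for kind in kinds:
        if kind == "disc":
            mask = r <= 0.35 * size
        elif kind == "ring":
            mask = (r <= 0.4 * size) & (r >= 0.25 * size)
        elif kind == "cross":
            w = 0.12 * size
            mask = ((np.abs(ii - c) <= w) | (np.abs(jj - c) <= w)) & (r <= 0.45 * size)
        elif kind == "star":
            ang = np.arctan2(ii - c, jj - c)
            mask = r <= 0.2 * size * (1.0 + 0.9 * np.cos(5 * ang) ** 2)
        elif kind == "glider":
            mask = np.zeros((size, size), dtype=bool)
            cell = max(size // 6, 1)
            for bi, bj in [(0, 1), (1, 2), (2, 0), (2, 1), (2, 2)]:
                mask[
                    (1 + bi) * cell : (2 + bi) * cell, (1 + bj) * cell : (2 + bj) * cell
                ] = True
        else:
            raise ValueError(f"unknown shape kind {kind!r}")
        colour = 0.25 + 0.75 * rng.random(3)
        img = np.zeros((size, size, 4))
        img[mask, :3] = colour
        img[mask, 3] = 1.0
        images.append(img)
    return images


def rotate_trajectory(
    data: TrainingData, angle: float, interpolation: str = "bilinear"
) -> TrainingData:
    """Rotate every frame about the lattice centre.

    Multiples of 90 degrees are exact index permutations; other angles use
    bilinear (order-1) interpolation with zero fill.
    """
    y = data.y
    a = angle % 360.0
    if np.isclose(a % 90.0, 0.0):
        k = int(round(a / 90.0)) % 4
        out = np.rot90(y, k=k, axes=(2, 3)).copy()
    else:
        order = {"nearest": 0, "bilinear": 1}[interpolation]
        out = ndimage.rotate(
            y, angle, axes=(3, 2), reshape=False, order=order, mode="constant", cval=0.0
        )
    return TrainingData(y=out, t=data.t, boundary=data.boundary)
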