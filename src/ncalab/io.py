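"""Configuration, model and trajectory serialisation.

Models are stored as a JSON manifest (architecture, kernel names in order,
update settings, seed) next to an ``.npz`` of the weight arrays; trajectories
go to HDF5 with axes fixed as ``(time, batch, row, col, channel)`` plus a
JSON sidecar of generation parameters.  A save -> load -> rollout cycle is
bit-identical to the original model's rollout under equal seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, Field

from .core import NCAParameters, UpdateConfig
from .kernels import KernelSet, standard_kernels

__all__ = [
    "ModelConfig",
    "TrainBlock",
    "RunConfig",
    "load_config",
    "dump_config",
    "save_model",
    "load_model",
    "export_trajectory",
    "import_trajectory",
]

TRAJECTORY_AXES = ("time", "batch", "row", "col", "channel")


class ModelConfig(BaseModel):
    """Architecture block of a run configuration."""

    C: int = 8
    C_obs: int = 2
    kernels: list[str] = Field(default_factory=lambda: ["identity", "laplacian"])
    activation: str = "relu"
    H: int | None = None  # defaults to 4C
    p: float = 0.0
    granularity: str = "per-element"


class TrainBlock(BaseModel):
    """Training block of a run configuration."""

    t: int = 16
    epochs: int = 300
    B: int = 1
    lr: float = 1e-3
    loss: str = "euclidean"
    seed: int = 0
    reinit_batch: int = 0


class RunConfig(BaseModel):
    """A complete, file-round-trippable experiment description."""

    task: str = "gray_scott"
    model: ModelConfig = Field(default_factory=ModelConfig)
    training: TrainBlock = Field(default_factory=TrainBlock)
    data: dict = Field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def save_model(
    theta: NCAParameters,
    path: str | Path,
    kernels: KernelSet,
    C_obs: int,
    update_cfg: UpdateConfig | None = None,
) -> None:
    """Write ``<path>.json`` (manifest) and ``<path>.npz`` (W1, W2, v)."""
    path = Path(path)
    update_cfg = update_cfg or UpdateConfig()
    manifest = {
        "C": theta.C,
        "C_obs": C_obs,
        "K": theta.K,
        "kernels": list(kernels.names),
        "H": theta.H,
        "activation": theta.activation,
        "p": update_cfg.p,
        "granularity": update_cfg.mask_granularity,
        "seed": update_cfg.seed,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    np.savez(path.with_suffix(".npz"), W1=theta.W1, W2=theta.W2, v=theta.v)


def load_model(path: str | Path):
    """Load a saved model; returns ``(theta, kernels, C_obs, update_cfg)``.

    Raises ``ValueError`` on any manifest/array shape mismatch.
    """
    path = Path(path)
    mpath = path.with_suffix(".json")
    apath = path.with_suffix(".npz")
    if not mpath.exists() or not apath.exists():
        raise FileNotFoundError(f"missing model files {mpath} / {apath}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    arrays = np.load(apath)
    C, K, H = manifest["C"], manifest["K"], manifest["H"]
    expected = {"W1": (C, H), "W2": (H, C * K), "v": (C,)}
    for name, shape in expected.items():
        if arrays[name].shape != shape:
            raise ValueError(
                f"array {name} has shape {arrays[name].shape}, manifest implies {shape}"
            )
    kernels = standard_kernels(manifest["kernels"])
    theta = NCAParameters(
        W2=arrays["W2"], W1=arrays["W1"], v=arrays["v"], activation=manifest["activation"]
    )
    cfg = UpdateConfig(
        p=manifest["p"], mask_granularity=manifest["granularity"], seed=manifest["seed"]
    )
    return theta, kernels, manifest["C_obs"], cfg


def _to_uint8(frame: np.ndarray) -> np.ndarray:
    return (np.clip(frame, 0.0, 1.0) * 255).round().astype(np.uint8)


def export_trajectory(
    trajectory: np.ndarray,
    directory: str | Path,
    C_obs: int,
    meta: dict | None = None,
    write_frames: bool = True,
) -> Path:
    """Write a ``(time, batch, row, col, channel)`` array to HDF5 + PNG frames.

    Observable channels are rendered per step: RGB(A) when ``C_obs`` is 3 or
    4, otherwise one grayscale image per channel.  A JSON sidecar records
    axes, shapes and any generation metadata; non-finite values are flagged
    there rather than silently written.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim == 4:  # single-copy convenience: (time, row, col, channel)
        arr = arr[:, None]
    if arr.ndim != 5:
        raise ValueError(f"trajectory must be 5-D {TRAJECTORY_AXES}, got shape {arr.shape}")
    with h5py.File(directory / "trajectory.h5", "w") as fh:
        ds = fh.create_dataset("states", data=arr)
        ds.attrs["axes"] = ",".join(TRAJECTORY_AXES)
        ds.attrs["C_obs"] = C_obs
    sidecar = {
        "axes": list(TRAJECTORY_AXES),
        "shape": list(arr.shape),
        "C_obs": C_obs,
        "finite": bool(np.all(np.isfinite(arr))),
        **(meta or {}),
    }
    with open(directory / "trajectory.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    if write_frames:
        obs = arr[..., :C_obs]
        lo, hi = float(obs.min()), float(obs.max())
        scale = (obs - lo) / (hi - lo) if hi > lo else np.zeros_like(obs)
        for m in range(arr.shape[0]):
            for r in range(arr.shape[1]):
                tag = f"step{m:04d}_b{r}"
                if C_obs in (3, 4):
                    iio.imwrite(directory / f"{tag}.png", _to_uint8(scale[m, r]))
                else:
                    for c in range(C_obs):
                        iio.imwrite(
                            directory / f"{tag}_c{c}.png", _to_uint8(scale[m, r, :, :, c])
                        )
    return directory / "trajectory.h5"


def import_trajectory(path: str | Path) -> np.ndarray:
    """Read back the HDF5 container written by :func:`export_trajectory`."""
    with h5py.File(path, "r") as fh:
        return fh["states"][...]
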