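"""Reading and writing the pipeline's artifacts.

Dynamic series travel as 4-D NIfTI (frame as 4th axis) with a JSON sidecar
holding the frame schedule — seconds on disk (the clinical convention),
minutes in memory — or as a single ``.npz`` archive.  Blood curves are
two-column CSV.  Run configuration is strict YAML: unknown keys are
rejected and ``load(save(cfg)) == cfg``.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import yaml

from .types import BloodInput, DynamicSeries, FrameSchedule

__all__ = [
    "read_series", "write_series", "read_blood", "write_blood",
    "RunConfig", "load_config", "save_config",
    "save_checkpoint", "load_checkpoint",
]


def _full_ext(path: str) -> str:
    for ext in (".nii.gz", ".nii", ".npz"):
        if path.endswith(ext):
            return ext
    return os.path.splitext(path)[1]


def _atomic_write(path: str, writer) -> None:
    """Write via a temp file (same directory, same extension so format
    sniffing works), then rename into place."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=_full_ext(path))
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)


def _sidecar_path(path: str) -> str:
    base = path
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    return base + ".json"


def _schedule_to_json(schedule: FrameSchedule) -> dict:
    half_life_s = (float(np.log(2.0) / schedule.decay_lambda * 60.0)
                   if schedule.decay_lambda > 0 else None)
    return {
        "starts_s": (schedule.starts * 60.0).tolist(),
        "ends_s": (schedule.ends * 60.0).tolist(),
        "half_life_s": half_life_s,
        "decay_corrected": bool(schedule.decay_corrected_input),
    }


def _schedule_from_json(d: dict) -> FrameSchedule:
    lam = (np.log(2.0) / (d["half_life_s"] / 60.0)
           if d.get("half_life_s") else 0.0)
    return FrameSchedule(
        starts=np.asarray(d["starts_s"]) / 60.0,
        ends=np.asarray(d["ends_s"]) / 60.0,
        decay_lambda=float(lam),
        decay_corrected_input=bool(d.get("decay_corrected", True)),
    )


def write_series(series: DynamicSeries, path: str) -> None:
    """Write a dynamic series as 4-D NIfTI (+ JSON schedule sidecar) or as a
    ``.npz`` archive, losslessly up to floating storage."""
    if path.endswith(".npz"):
        _atomic_write(path, lambda tmp: np.savez(tmp, **{
            "frames": series.frames,
            "starts_s": series.schedule.starts * 60.0,
            "ends_s": series.schedule.ends * 60.0,
            "decay_lambda": series.schedule.decay_lambda,
            "decay_corrected": series.schedule.decay_corrected_input,
        }))
        return
    T, H, W = series.frames.shape
    data = np.transpose(series.frames, (1, 2, 0))[:, :, None, :]  # H,W,1,T
    img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
    _atomic_write(path, lambda tmp: nib.save(img, tmp))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(_schedule_to_json(series.schedule), fh, indent=1)


def read_series(path: str) -> DynamicSeries:
    """Inverse of :func:`write_series`; raises on a missing sidecar or a
    frame-count mismatch between image and schedule."""
    if path.endswith(".npz"):
        with np.load(path) as z:
            schedule = FrameSchedule(
                starts=z["starts_s"] / 60.0, ends=z["ends_s"] / 60.0,
                decay_lambda=float(z["decay_lambda"]),
                decay_corrected_input=bool(z["decay_corrected"]))
            frames = z["frames"]
    else:
        sidecar = _sidecar_path(path)
        if not os.path.exists(sidecar):
            raise FileNotFoundError(
                f"missing schedule sidecar {sidecar!r} for {path!r}")
        with open(sidecar) as fh:
            schedule = _schedule_from_json(json.load(fh))
        data = np.asanyarray(nib.load(path).dataobj)
        if data.ndim == 4:
            data = data[:, :, 0, :]
        frames = np.transpose(data, (2, 0, 1)).astype(float)
    if frames.shape[0] != schedule.n_frames:
        raise ValueError(
            f"frame-count mismatch: image has {frames.shape[0]} frames, "
            f"schedule lists {schedule.n_frames}")
    return DynamicSeries(frames=frames, schedule=schedule)


def write_blood(blood: BloodInput, path: str) -> None:
    arr = np.column_stack([blood.times, blood.values])
    _atomic_write(path, lambda tmp: np.savetxt(
        tmp, arr, delimiter=",", header="time_min,value", comments=""))


def read_blood(path: str) -> BloodInput:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return BloodInput(times=arr[:, 0], values=arr[:, 1])


def write_map(image: np.ndarray, path: str) -> None:
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float32),
                          affine=np.eye(4))
    _atomic_write(path, lambda tmp: nib.save(img, tmp))


def read_map(path: str) -> np.ndarray:
    return np.asanyarray(nib.load(path).dataobj).astype(float)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything a training/simulation run needs, serializable to YAML."""

    seed: int = 0
    variant: str = "full"          # "full" | "without_model"
    image_size: int = 64
    n_train_slices: int = 8
    n_iterations: int = 600
    channel_scale: float = 0.0625  # 1.0 = full-width 64..1024 channels
    head_hidden: tuple = (64, 32)
    grid_dt: float = 0.2           # kinetic-layer quadrature spacing (min)
    noise_scale: float = 2.0
    jitter: float = 0.10
    weight_kg: float = 63.0
    dose_MBq: float = 300.0
    n_tail: int = 13
    augment: bool = True
    lambda_weight: float = 1.0
    huber_delta: float = 1.0
    initial_lr: float = 1e-4
    decay_every_iters: int = 10_000
    decay_factor: float = 0.1
    lr_floor: float = 1e-7
    clip_norm: float | None = None

    def __post_init__(self):
        if self.variant not in ("full", "without_model"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16")
        object.__setattr__(self, "head_hidden", tuple(self.head_hidden))


def save_config(cfg: RunConfig, path: str) -> None:
    d = dataclasses.asdict(cfg)
    d["head_hidden"] = list(d["head_hidden"])
    _atomic_write(path, lambda tmp: open(tmp, "w").write(
        yaml.safe_dump(d, sort_keys=True)))


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**d)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path: str, meta: dict) -> None:
    """Model weights + JSON metadata (architecture, seed, schedule
    fingerprint) in one npz archive."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)

    _atomic_write(path, lambda tmp: np.savez(tmp, **arrays))


def load_checkpoint(path: str):
    """Returns ``(list_of_weight_arrays, meta_dict)``."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        n = len([k for k in z.files if k.startswith("param_")])
        weights = [z[f"param_{i}"] for i in range(n)]
    return weights, meta


def restore_weights(model, weights: list) -> None:
    params = model.params()
    if len(params) != len(weights):
        raise ValueError("checkpoint does not match model architecture")
    for p, w in zip(params, weights):
        if p.value.shape != w.shape:
            raise ValueError("checkpoint does not match model architecture")
        p.value[...] = w.astype(p.value.dtype)
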