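"""Composite loss, optimiser schedule, and the training loop.

The total loss is ``loss = loss_SUV + lambda * loss_diff``:

* ``loss_SUV`` — mean Huber loss between predicted and measured frames,
  evaluated over the *target* frames only (the last 6 by default; the first
  22 frames are the network's input and are never supervised).
* ``loss_diff`` — mean Huber loss between successive-frame differences of
  the Patlak ordinate ``y = pred/Cp`` and of ``Ki * x`` over the linear
  portion (last 13 frames by default), anchoring the prediction's Patlak
  slope.  ``Ki`` is fitted from the current prediction by OLS and treated as
  a constant per step (no gradient flows through it); a fixed reference Ki
  map may be supplied instead.

Both networks (hybrid and model-free) train under the same losses and Adam
schedule: initial learning rate 1e-4, divided by 10 every 10,000 iterations,
floored at 1e-7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn, patlak
from .network import HybridModel, WithoutModelNet
from .types import BloodInput

__all__ = [
    "LossConfig", "OptimizerConfig", "huber", "huber_grad",
    "loss_suv", "loss_diff", "total_loss", "lr_at", "train",
]


@dataclass(frozen=True)
class LossConfig:
    huber_delta: float = 1.0
    lambda_weight: float = 1.0
    #: indices of the supervised frames (None -> last 6)
    target_frame_indices: tuple | None = None
    #: indices of the Patlak linear portion (None -> last 13)
    linear_frame_indices: tuple | None = None
    #: "prediction": Ki refitted from the current prediction each step;
    #: "reference": a fixed Ki map passed to the loss
    ki_source: str = "prediction"

    def __post_init__(self):
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if self.huber_delta <= 0:
            raise ValueError("huber_delta must be > 0")

    def targets(self, n_frames: int) -> np.ndarray:
        if self.target_frame_indices is not None:
            return np.asarray(self.target_frame_indices, dtype=int)
        return np.arange(n_frames - 6, n_frames)

    def linear(self, n_frames: int) -> np.ndarray:
        if self.linear_frame_indices is not None:
            return np.asarray(self.linear_frame_indices, dtype=int)
        return np.arange(n_frames - 13, n_frames)


@dataclass(frozen=True)
class OptimizerConfig:
    initial_lr: float = 1e-4
    decay_every_iters: int = 10_000
    decay_factor: float = 0.1
    lr_floor: float = 1e-7
    epochs: int = 10
    seed: int = 0
    #: global gradient-norm clip; None disables. Single-slice steps have
    #: heavy-tailed gradient noise, so small-batch runs benefit from a cap.
    clip_norm: float | None = None


def huber(residual: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Elementwise Huber loss: r^2/2 below delta, delta*(|r| - delta/2) above."""
    r = np.abs(residual)
    return np.where(r <= delta, 0.5 * r * r, delta * (r - 0.5 * delta))


def huber_grad(residual: np.ndarray, delta: float = 1.0) -> np.ndarray:
    return np.clip(residual, -delta, delta)


def loss_suv(pred: np.ndarray, truth: np.ndarray, cfg: LossConfig = LossConfig()):
    """Mean Huber loss over target frames x pixels.

    ``pred`` holds all predicted frames (T, H, W); ``truth`` either matches
    it or holds only the target frames.  Returns ``(loss, dpred)`` with
    ``dpred`` shaped like ``pred`` (zero on non-target frames).
    """
    idx = cfg.targets(pred.shape[0])
    tgt = truth[idx] if truth.shape[0] == pred.shape[0] else truth
    if tgt.shape != pred[idx].shape:
        raise ValueError("prediction/truth shapes do not match on target frames")
    resid = pred[idx] - tgt
    norm = resid.size
    value = float(huber(resid, cfg.huber_delta).sum() / norm)
    dpred = np.zeros_like(pred)
    dpred[idx] = huber_grad(resid, cfg.huber_delta) / norm
    return value, dpred


def loss_diff(pred: np.ndarray, blood: BloodInput, schedule,
              cfg: LossConfig = LossConfig(),
              ki_ref: np.ndarray | None = None):
    """Patlak time-difference loss over the linear-portion frames.

    Compares first differences of ``y = pred/Cp`` with first differences of
    ``Ki * x`` (both along the linear frames), Huber-averaged over
    ``T_linear * M * N``.  ``Ki`` is the per-voxel OLS Patlak slope of the
    current prediction (detached: no gradient flows through it) unless a
    fixed ``ki_ref`` map is given.  Returns ``(loss, dpred)``.
    """
    idx = cfg.linear(pred.shape[0])
    if len(idx) < 2:
        raise ValueError("need at least 2 linear-portion frames")
    mid = schedule.mid_times[idx]
    x, cp = patlak.patlak_x(blood, mid)
    y = pred[idx] / cp[:, None, None]
    if ki_ref is None:
        xc = x - x.mean()
        ki = np.tensordot(xc, y, axes=(0, 0)) / (xc @ xc)  # detached OLS slope
    else:
        ki = ki_ref
    dy = np.diff(y, axis=0)
    dx = np.diff(x)
    resid = dy - ki[None] * dx[:, None, None]
    T_lin = len(idx)
    norm = T_lin * pred.shape[1] * pred.shape[2]
    value = float(huber(resid, cfg.huber_delta).sum() / norm)
    gres = huber_grad(resid, cfg.huber_delta) / norm
    dpred = np.zeros_like(pred)
    dy_grad = np.zeros_like(y)
    dy_grad[1:] += gres
    dy_grad[:-1] -= gres
    dpred[idx] = dy_grad / cp[:, None, None]
    return value, dpred


def total_loss(pred: np.ndarray, truth: np.ndarray, blood: BloodInput,
               schedule, cfg: LossConfig = LossConfig(),
               ki_ref: np.ndarray | None = None):
    """``loss_SUV + lambda * loss_diff``; returns (value, dpred, parts)."""
    ls, dls = loss_suv(pred, truth, cfg)
    if cfg.lambda_weight > 0:
        ld, dld = loss_diff(pred, blood, schedule, cfg, ki_ref=ki_ref)
    else:
        ld, dld = 0.0, 0.0
    value = ls + cfg.lambda_weight * ld
    dpred = dls + cfg.lambda_weight * dld
    return value, dpred, {"loss_suv": ls, "loss_diff": ld}


def lr_at(iteration: int, cfg: OptimizerConfig = OptimizerConfig()) -> float:
    """Step-decay schedule: lr = initial * factor^(iteration // every),
    clamped at the floor."""
    lr = cfg.initial_lr * cfg.decay_factor ** (iteration // cfg.decay_every_iters)
    return max(lr, cfg.lr_floor)


def _augment(frames: np.ndarray, rng) -> np.ndarray:
    """Random dihedral transform of a (T, H, W) stack.

    Rotations and flips are exact symmetries of the per-voxel kinetics (the
    network itself is convolutional), so they enlarge layout diversity for
    free."""
    k = int(rng.integers(4))
    out = np.rot90(frames, k, axes=(1, 2))
    if rng.integers(2):
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


def train(model, dataset: list, loss_cfg: LossConfig = LossConfig(),
          opt_cfg: OptimizerConfig = OptimizerConfig(),
          n_iterations: int | None = None, augment: bool = False,
          callback=None) -> dict:
    """Seeded training loop over a dataset of slices.

    ``dataset`` is a list of dicts with keys ``frames`` (noisy (T, H, W)
    series values), ``blood`` (:class:`BloodInput`), and optionally
    ``ki_ref``.  Each iteration draws one slice (seeded RNG), optionally
    applies a random rotation/flip (``augment``), runs the forward/backward
    pass and one Adam step at the scheduled learning rate.
    ``n_iterations`` defaults to ``epochs * len(dataset)``.

    Works for both :class:`HybridModel` (frames in -> all frames out) and
    :class:`WithoutModelNet` (frames in -> target frames out; its prediction
    is completed with the known input frames before the losses so both
    variants share the identical loss definition).

    Returns a history dict with per-iteration ``loss``/``loss_suv``/
    ``loss_diff``/``lr`` arrays.
    """
    rng = np.random.default_rng(opt_cfg.seed)
    params = model.params()
    opt = nn.Adam(params)
    if n_iterations is None:
        n_iterations = opt_cfg.epochs * len(dataset)
    hist = {"loss": [], "loss_suv": [], "loss_diff": [], "lr": []}
    is_hybrid = isinstance(model, HybridModel)
    n_in = model.encoder_spec.input_frames

    for it in range(n_iterations):
        sample = dataset[rng.integers(len(dataset))]
        frames = sample["frames"]
        if augment:
            frames = _augment(frames, rng)
        blood = sample["blood"]
        schedule = sample["schedule"]
        inp = frames[:n_in]
        lr = lr_at(it, opt_cfg)
        model.zero_grad()
        if is_hybrid:
            pred, _ = model.forward(inp)
            value, dpred, parts = total_loss(
                pred, frames, blood, schedule, loss_cfg,
                ki_ref=sample.get("ki_ref") if loss_cfg.ki_source == "reference" else None)
            model.backward(dpred)
        else:
            tail = model.forward(inp)
            pred = np.concatenate([inp, tail], axis=0)
            value, dpred, parts = total_loss(
                pred, frames, blood, schedule, loss_cfg,
                ki_ref=sample.get("ki_ref") if loss_cfg.ki_source == "reference" else None)
            model.backward(dpred[n_in:])
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it}")
        if opt_cfg.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
            if total > opt_cfg.clip_norm:
                scale = opt_cfg.clip_norm / total
                for p in params:
                    p.grad *= scale
        opt.step(lr)
        hist["loss"].append(value)
        hist["loss_suv"].append(parts["loss_suv"])
        hist["loss_diff"].append(parts["loss_diff"])
        hist["lr"].append(lr)
        if callback is not None:
            callback(it, value)
    return {k: np.asarray(v) for k, v in hist.items()}
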