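"""Patch-based training loop: sampling, augmentation, Adam, early stopping.

Training follows the schedule style of the original experiments: every
iteration draws a random patch from the training volume (with 50%-probability
flip/rotation augmentation), the learning rate drops by a fixed factor on a
fixed epoch period, and training stops early when the validation loss fails
to decrease for more than ``patience_no_decrease`` epochs or increases for
more than ``stop_on_increase`` consecutive epochs.  The parameters achieving
the best validation loss are restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .models import Model

__all__ = [
    "TrainingConfig", "TrainingResult", "Adam",
    "sample_patch", "augment_patch", "train", "predict_tiled",
]

#: the four augmentation operations; one is chosen uniformly when augmenting
AUGMENT_OPS = ("reflect_x", "reflect_y", "rot90_z", "reflect_x_rot90_z")


@dataclass
class TrainingConfig:
    initial_lr: float = 1e-3
    lr_drop_factor: float = 0.75
    lr_drop_period_epochs: int = 5
    minibatch_size: int = 2
    patch_size_voxels: tuple[int, int, int] = (32, 32, 16)
    patches_per_epoch: int = 50
    max_epochs: int = 15
    patience_no_decrease: int = 2
    stop_on_increase: int = 1
    augment: bool = True
    seed: int = 0

    def to_dict(self):
        return asdict(self)


@dataclass
class TrainingResult:
    model: Model
    train_loss: list[float]
    val_loss: list[float]
    lr_schedule: list[float]
    best_epoch: int
    stopped_early: bool


class Adam:
    """Adam optimizer with the standard default moment parameters."""

    def __init__(self, model: Model, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(model.get_param(k))
                  for k in model.parameters()}
        self.v = {k: np.zeros_like(model.get_param(k))
                  for k in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k in self.model.parameters():
            g = self.model.get_grad(k)
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.model.get_param(k)[...] -= \
                self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sample_patch(volume: np.ndarray, patch_size, rng: np.random.Generator):
    """Uniformly random patch origin; returns (origin, view).

    ``volume`` is (x,y,z) or (C,x,y,z); the patch covers the spatial axes.
    """
    v = np.asarray(volume)
    spatial = v.shape[-3:]
    ps = tuple(patch_size)
    if any(p > s for p, s in zip(ps, spatial)):
        raise ValueError(f"patch {ps} larger than volume {spatial}")
    origin = tuple(int(rng.integers(0, s - p + 1))
                   for s, p in zip(spatial, ps))
    sl = tuple(slice(o, o + p) for o, p in zip(origin, ps))
    return origin, v[(...,) + sl]


def _apply_op(patch: np.ndarray, op: str) -> np.ndarray:
    """Apply a named flip/rotation to the spatial axes (last three)."""
    ax_x, ax_y = patch.ndim - 3, patch.ndim - 2
    if op == "identity":
        return patch
    if op == "reflect_x":
        return np.flip(patch, axis=ax_x)
    if op == "reflect_y":
        return np.flip(patch, axis=ax_y)
    if op == "rot90_z":  # counterclockwise in the x-y plane
        return np.rot90(patch, k=1, axes=(ax_x, ax_y))
    if op == "reflect_x_rot90_z":
        return np.rot90(np.flip(patch, axis=ax_x), k=1, axes=(ax_x, ax_y))
    raise ValueError(f"unknown augmentation {op!r}")


def augment_patch(image_patch: np.ndarray, target_patch: np.ndarray,
                  rng: np.random.Generator):
    """With probability 1/2 apply one of the four flip/rotate operations
    (chosen uniformly) identically to both patches; otherwise identity."""
    if rng.random() < 0.5:
        op = AUGMENT_OPS[int(rng.integers(0, len(AUGMENT_OPS)))]
    else:
        op = "identity"
    return _apply_op(image_patch, op), _apply_op(target_patch, op)


def _as_chan(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v[None] if v.ndim == 3 else v


def train(model: Model, train_input: np.ndarray, train_target: np.ndarray,
          cfg: TrainingConfig, loss_with_grad,
          val_input: np.ndarray | None = None,
          val_target: np.ndarray | None = None,
          verbose: bool = False) -> TrainingResult:
    """Train ``model`` on random patches of one volume pair.

    ``loss_with_grad(pred, target) -> (scalar, grad)`` defines the
    objective.  ``train_input``/``train_target`` are (C,x,y,z) (or (x,y,z))
    volumes on the same grid; validation volumes, when given, are evaluated
    whole once per epoch and drive the early-stopping rule, otherwise the
    epoch-mean training loss is used.
    """
    rng = np.random.default_rng(cfg.seed)
    tin, ttar = _as_chan(train_input), _as_chan(train_target)
    vin = _as_chan(val_input) if val_input is not None else None
    vtar = _as_chan(val_target) if val_target is not None else None

    opt = Adam(model, lr=cfg.initial_lr)
    history_t, history_v, lrs = [], [], []
    best_loss, best_state, best_epoch = np.inf, model.state_dict(), 0
    no_decrease = 0
    increases = 0
    prev_val = np.inf
    stopped_early = False
    iters = max(1, cfg.patches_per_epoch // cfg.minibatch_size)

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.initial_lr * cfg.lr_drop_factor ** \
            (epoch // cfg.lr_drop_period_epochs)
        lrs.append(opt.lr)
        epoch_losses = []
        for _ in range(iters):
            xs, ys = [], []
            for _ in range(cfg.minibatch_size):
                origin, xp = sample_patch(tin, cfg.patch_size_voxels, rng)
                sl = tuple(slice(o, o + p) for o, p in
                           zip(origin, cfg.patch_size_voxels))
                yp = ttar[(...,) + sl]
                if cfg.augment:
                    xp, yp = augment_patch(xp, yp, rng)
                xs.append(xp)
                ys.append(yp)
            xb = np.stack(xs)
            yb = np.stack(ys)
            pred = model.forward(xb, training=True)
            loss, grad = loss_with_grad(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        history_t.append(train_loss)

        if vin is not None:
            vpred = model.forward(vin[None], training=False)
            val_loss = float(loss_with_grad(vpred, vtar[None])[0])
        else:
            val_loss = train_loss
        history_v.append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {train_loss:.5g} val {val_loss:.5g} "
                  f"lr {opt.lr:.3g}")

        if val_loss < best_loss - 1e-12:
            best_loss, best_epoch = val_loss, epoch
            best_state = model.state_dict()
            no_decrease = 0
        else:
            no_decrease += 1
        increases = increases + 1 if val_loss > prev_val else 0
        prev_val = val_loss
        if no_decrease > cfg.patience_no_decrease or \
                increases > cfg.stop_on_increase:
            stopped_early = True
            break

    model.load_state_dict(best_state)
    return TrainingResult(model, history_t, history_v, lrs,
                          best_epoch, stopped_early)


def early_stop_epoch(val_losses, patience_no_decrease: int = 2,
                     stop_on_increase: int = 1) -> int | None:
    """Index of the epoch after which training would stop, else None.

    Stop when the running best has not improved for more than
    ``patience_no_decrease`` epochs, or the loss has risen for more than
    ``stop_on_increase`` consecutive epochs.
    """
    best = np.inf
    no_decrease = 0
    increases = 0
    prev = np.inf
    for i, v in enumerate(val_losses):
        if v < best - 1e-12:
            best = v
            no_decrease = 0
        else:
            no_decrease += 1
        increases = increases + 1 if v > prev else 0
        prev = v
        if no_decrease > patience_no_decrease or increases > stop_on_increase:
            return i
    return None


def predict_tiled(model: Model, volume: np.ndarray, patch_size,
                  overlap=(8, 8, 4), **forward_kwargs) -> np.ndarray:
    """Apply a fully convolutional model patch-by-patch over a volume.

    Tiles of ``patch_size`` are stepped by ``patch - overlap``; the final
    tile along each axis is shifted flush with the volume end so coverage is
    complete.  Voxels covered by several tiles take the uniform average.
    Returns (C_out, x, y, z) matching the input spatial shape.
    """
    v = _as_chan(volume)
    spatial = v.shape[-3:]
    ps = tuple(patch_size)
    if any(p > s for p, s in zip(ps, spatial)):
        raise ValueError(f"patch {ps} larger than volume {spatial}")
    steps = tuple(max(p - o, 1) for p, o in zip(ps, overlap))
    origins = []
    for s, p, st in zip(spatial, ps, steps):
        o = list(range(0, s - p + 1, st))
        if o[-1] != s - p:
            o.append(s - p)
        origins.append(o)

    out = None
    weight = np.zeros(spatial)
    for ox in origins[0]:
        for oy in origins[1]:
            for oz in origins[2]:
                sl = (slice(ox, ox + ps[0]), slice(oy, oy + ps[1]),
                      slice(oz, oz + ps[2]))
                pred = model.forward(v[(None, ...) + sl], training=False,
                                     **forward_kwargs)[0]
                if out is None:
                    out = np.zeros((pred.shape[0],) + spatial)
                out[(slice(None),) + sl] += pred
                weight[sl] += 1.0
    out /= weight[None]
    return out
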