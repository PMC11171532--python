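"""Unsupervised training of the registration network.

The loss is the masked image-similarity term plus a diffusion-style
smoothness penalty on the displacement field,

    L(f, m, phi) = L_mse(f, m o phi) + lambda * L_ppm(phi),

where ``L_mse`` is the mean squared intensity difference between the
fixed and transformed images over the breast + pectoral mask and
``L_ppm`` is the per-pixel misalignment: the mean squared forward
difference of the displacement components, per spatial direction (a
field linear in the column index with slope c scores c^2/2).  Defaults
follow the clinical protocol: 800 epochs, batch 32, lambda = 1, Adam at
2e-4 with per-epoch cosine annealing to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import autodiff as ad
from .model import RegistrationUNet, UNetConfig

__all__ = [
    "TrainConfig",
    "LearningCurve",
    "loss_mse",
    "loss_smoothness",
    "total_loss",
    "cosine_annealed_lr",
    "Adam",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 800
    batch_size: int = 32
    lambda_smooth: float = 1.0
    base_lr: float = 2e-4
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")


@dataclass
class LearningCurve:
    """Per-epoch mean training and validation losses."""

    train: list = dc_field(default_factory=list)
    val: list = dc_field(default_factory=list)


def loss_mse(fixed: np.ndarray, warped: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared intensity difference over mask pixels."""
    fixed = np.asarray(fixed)
    warped = np.asarray(warped)
    mask = np.asarray(mask, dtype=bool)
    if fixed.shape != warped.shape or fixed.shape != mask.shape:
        raise ValueError("fixed, warped and mask must share one shape")
    if not mask.any():
        raise ValueError("mask is empty")
    d = fixed[mask] - warped[mask]
    return float(np.mean(d * d))


def loss_smoothness(field: np.ndarray) -> float:
    """Per-pixel misalignment of a ``(2, H, W)`` displacement field.

    Squared forward differences of both components, averaged over the
    valid positions and components of each spatial direction; the two
    directional means are summed.
    """
    field = np.asarray(field)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) field, got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    dr = np.diff(field, axis=1)
    dc = np.diff(field, axis=2)
    total = 0.0
    if dr.size:
        total += float(np.mean(dr * dr))
    if dc.size:
        total += float(np.mean(dc * dc))
    return total


def total_loss(
    fixed: np.ndarray,
    warped: np.ndarray,
    field: np.ndarray,
    mask: np.ndarray,
    lambda_smooth: float = 1.0,
) -> float:
    """Composite loss: masked similarity plus weighted smoothness."""
    return loss_mse(fixed, warped, mask) + lambda_smooth * loss_smoothness(field)


def cosine_annealed_lr(epoch: int, config: TrainConfig) -> float:
    """Cosine-annealed learning rate: base at epoch 0, zero at the end."""
    if epoch < 0 or epoch > config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    return config.base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))


class Adam:
    """Adam with bias correction; the learning rate is set per step."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= (lr * mh / (np.sqrt(vh) + self.eps)).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _stack(pairs):
    fixed = np.stack([p.fixed for p in pairs])[:, None].astype(np.float32)
    moving = np.stack([p.flipped for p in pairs])[:, None].astype(np.float32)
    masks = np.stack([p.mask for p in pairs])[:, None].astype(np.float32)
    return fixed, moving, masks


def _batch_loss(model, fixed, moving, masks, lam, with_grad=True):
    x = ad.Tensor(np.concatenate([fixed, moving], axis=1))
    flow = model.forward(x)
    if not with_grad:
        flow = ad.Tensor(flow.data)
    warped = ad.warp_bilinear(ad.Tensor(moving), flow)
    loss = ad.masked_mse(warped, fixed, masks) + lam * ad.smoothness_penalty(flow)
    return loss


def train(
    pairs,
    val_pairs,
    config: TrainConfig = TrainConfig(),
    unet_config: UNetConfig | None = None,
    model: RegistrationUNet | None = None,
    verbose: bool = False,
):
    """Train the registration U-Net on preprocessed pairs.

    Runs Adam on the composite loss with per-epoch cosine annealing,
    logs mean train/validation losses each epoch (the validation pass
    performs no parameter updates), keeps the best-validation weights
    and restores them on return.  Seeded and reproducible on one device.

    Returns ``(model, LearningCurve)``.
    """
    if len(pairs) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = RegistrationUNet(
            unet_config or UNetConfig(), seed=int(rng.integers(0, 2**31 - 1))
        )
    fixed, moving, masks = _stack(pairs)
    has_val = val_pairs is not None and len(val_pairs) > 0
    if has_val:
        vfixed, vmoving, vmasks = _stack(val_pairs)
    opt = Adam(model.parameters())
    curve = LearningCurve()
    lam = config.lambda_smooth
    n = len(pairs)
    best_val, best_state = np.inf, None
    for epoch in range(config.epochs):
        lr = cosine_annealed_lr(epoch, config)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss = _batch_loss(model, fixed[idx], moving[idx], masks[idx], lam)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(loss.item())
        curve.train.append(float(np.mean(losses)))
        if has_val:
            vlosses = []
            for start in range(0, len(val_pairs), config.batch_size):
                sl = slice(start, start + config.batch_size)
                vloss = _batch_loss(
                    model, vfixed[sl], vmoving[sl], vmasks[sl], lam, with_grad=False
                )
                vlosses.append(vloss.item() * (sl.indices(len(val_pairs))[1] - start))
            curve.val.append(float(np.sum(vlosses) / len(val_pairs)))
            if curve.val[-1] < best_val:
                best_val = curve.val[-1]
                best_state = [p.data.copy() for p in model.parameters()]
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} lr={lr:.2e} train={curve.train[-1]:.5f}"
            if has_val:
                msg += f" val={curve.val[-1]:.5f}"
            print(msg)
    if best_state is not None:
        for p, w in zip(model.parameters(), best_state):
            p.data = w
    return model, curve
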