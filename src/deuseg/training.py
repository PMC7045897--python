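"""Dice-loss training of the segmentation network.

The objective is the soft Dice loss between the sigmoid probability map and
the binary gold mask, optimized with Adam at batch size 1.  Per-epoch
augmentation applies a horizontal flip (probability 0.5) and a spatial
rescale, identically to both input channels and the mask; the mask path is
nearest-neighbour so binarity survives.  All randomness — weight
initialization is the network's, shuffling and augmentation are here —
flows from the configured seed, so runs are reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import NetworkHandle
from .nn.optim import Adam
from .preprocess import pad_crop

__all__ = ["TrainConfig", "TrainingHistory", "dice_loss", "dice_loss_grad",
           "augment", "train"]


@dataclass
class TrainConfig:
    """Training hyperparameters.  The reference regime is Adam at learning
    rate 1e-4, batch size 1, 200 epochs, flip/rescale augmentation."""

    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 1
    augment: bool = True
    rescale_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0
    binarize_threshold: float = 0.5
    dice_smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        lo, hi = self.rescale_range
        if not (0 < lo <= hi):
            raise ValueError("rescale_range must satisfy 0 < lower <= upper")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.dice_smooth < 0:
            raise ValueError("dice_smooth must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch record of a training run."""

    losses: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    seed: int = 0


def dice_loss(prob_map: np.ndarray, gold: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss 1 - (2·Σpg + s) / (Σp + Σg + s), in [0, 1]."""
    loss, _ = dice_loss_grad(prob_map, gold, smooth)
    return loss


def dice_loss_grad(prob_map: np.ndarray, gold: np.ndarray, smooth: float = 1.0):
    """Soft Dice loss and its gradient w.r.t. the probability map."""
    p = np.asarray(prob_map, dtype=np.float64)
    g = np.asarray(gold, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prob {p.shape} vs gold {g.shape}")
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + smooth
    num = 2.0 * inter + smooth
    loss = 1.0 - num / denom
    grad = -(2.0 * g * denom - num) / denom**2
    return loss, grad


def _rescale_2d(img: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom a slice about its center and pad/crop back to the original size."""
    out_shape = img.shape
    zoomed = ndimage.zoom(img.astype(np.float64), factor, order=order,
                          mode="grid-constant", cval=0.0, grid_mode=True)
    return np.asarray(pad_crop(zoomed, out_shape))


def augment(sample, rng: np.random.Generator, cfg: TrainConfig):
    """Flip/rescale augmentation; geometric parameters are drawn once per
    sample and applied identically to all channels and the mask."""
    x, y = sample
    flip = rng.random() < 0.5
    lo, hi = cfg.rescale_range
    factor = float(rng.uniform(lo, hi))
    if flip:
        x = x[..., ::-1].copy()
        y = y[..., ::-1].copy()
    if factor != 1.0:
        x = np.stack([_rescale_2d(c, factor, order=1) for c in x]).astype(np.float32)
        y = (_rescale_2d(y, factor, order=0) >= 0.5).astype(np.float32)
    return x, y


def train(handle: NetworkHandle, dataset, cfg: TrainConfig,
          validation=None):
    """Train the network on per-slice samples.

    ``dataset`` is a non-empty list of ``(input, mask)`` pairs with input
    shape (C, H, W) matching the network and H×W equal to the configured
    input size.  Returns the handle (final-epoch weights, no checkpoint
    selection) and the training history.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    net = handle.network
    in_size = tuple(net.cfg.input_size)
    for i, (x, y) in enumerate(dataset):
        if x.shape[0] != net.in_channels or x.shape[1:] != in_size or y.shape != in_size:
            raise ValueError(
                f"sample {i}: input {x.shape} / mask {y.shape} incompatible with "
                f"network ({net.in_channels}, {in_size[0]}, {in_size[1]})")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory(seed=cfg.seed)

    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(dataset))
        losses = []
        pending = 0
        opt.zero_grad()
        for j, idx in enumerate(order):
            x, y = dataset[idx]
            if cfg.augment:
                x, y = augment((x, y), rng, cfg)
            prob = net.forward(x)
            loss, d_prob = dice_loss_grad(prob, y, cfg.dice_smooth)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, sample {j}")
            net.backward(d_prob)
            losses.append(loss)
            pending += 1
            if pending == cfg.batch_size or j == len(order) - 1:
                opt.step()
                opt.zero_grad()
                pending = 0
        history.losses.append(float(np.mean(losses)))
        if validation:
            from .evaluate import evaluate_patient  # noqa: PLC0415
            from .postprocess import binarize
            dscs = []
            for x, y in validation:
                pred = binarize(net.forward(x), cfg.binarize_threshold)
                dscs.append(evaluate_patient(pred, y.astype(np.uint8))["dsc"])
            history.val_dsc.append(float(np.mean(dscs)))
        history.epoch_seconds.append(time.perf_counter() - t0)
    return handle, history
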