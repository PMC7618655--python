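"""Seeded Adam training loop minimizing wing loss on decoded coordinates."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import constant
from .hourglass import HourglassNet
from .layers import Adam
from .losses import WingLossParams

__all__ = ["TrainConfig", "TrainSample", "train_stage"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 1e-4  # reference setting; desk-scale runs use more
    batch_size: int = 8
    seed: int = 0
    wing: WingLossParams = WingLossParams()
    # weight of the auxiliary heatmap-regression term (squared error of the
    # response maps against unit-amplitude Gaussian targets).  The primary
    # loss is wing on the decoded coordinates; the auxiliary term keeps the
    # per-landmark maps unimodal, which coordinate loss alone does not.
    heatmap_aux_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# (image in the stage's frame, target landmark coordinates in input pixels)
TrainSample = Tuple[np.ndarray, np.ndarray]


def _stack(dataset: Sequence[TrainSample]) -> Tuple[np.ndarray, np.ndarray]:
    images = np.stack([np.asarray(img, dtype=np.float32) for img, _ in dataset])
    targets = np.stack([np.asarray(t, dtype=np.float32) for _, t in dataset])
    return images, targets


def _gaussian_targets(
    targets: np.ndarray, input_size: int, stride: int, sigma: float
) -> np.ndarray:
    """Unit-amplitude Gaussian maps centred on each target coordinate."""
    side = input_size // stride
    xs = np.arange(side)
    mx = (targets[..., 0] + 0.5) / stride - 0.5  # (B, K)
    my = (targets[..., 1] + 0.5) / stride - 0.5
    dx2 = (xs[None, None, None, :] - mx[:, :, None, None]) ** 2
    dy2 = (xs[None, None, :, None] - my[:, :, None, None]) ** 2
    return np.exp(-(dx2 + dy2) / (2.0 * sigma**2)).astype(np.float32)


def _batch_loss(model, images, targets, hm_targets, wing, aux_weight):
    logits = model.forward(images)
    map_xy = logits.soft_argmax(model.config.softargmax_beta)
    s = float(model.config.heatmap_stride)
    coords = map_xy.scale(s) + constant(np.float32(0.5 * s - 0.5))
    loss = coords.wing_loss_to(targets, wing.w, wing.epsilon)
    if aux_weight > 0:
        diff = logits + constant(-hm_targets)
        n_spatial = hm_targets.shape[2] * hm_targets.shape[3]
        loss = loss + (diff * diff).mean().scale(aux_weight * n_spatial)
    return loss


def _eval_loss(
    model: HourglassNet, images: np.ndarray, targets: np.ndarray, wing: WingLossParams,
    batch_size: int,
) -> float:
    """Validation loss: wing on decoded coordinates (no auxiliary term)."""
    total, count = 0.0, 0
    for start in range(0, len(images), batch_size):
        sl = slice(start, start + batch_size)
        coords = model.predict_coords(images[sl])
        loss = coords.wing_loss_to(targets[sl], wing.w, wing.epsilon)
        n = len(images[sl])
        total += float(loss.data) * n
        count += n
    return total / count


def train_stage(
    model: HourglassNet,
    dataset: Sequence[TrainSample],
    config: TrainConfig,
    val_dataset: Optional[Sequence[TrainSample]] = None,
    log_path: Optional[Path] = None,
) -> List[dict]:
    """Train in place; returns the per-epoch loss history.

    History entries: ``{"epoch", "train_loss", "val_loss"}`` where
    ``train_loss`` is the mean minibatch loss of the epoch and
    ``val_loss`` the post-epoch validation loss (``nan`` if no
    validation set was given).  Epoch 0 records the pre-training losses.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    images, targets = _stack(dataset)
    hm_targets = _gaussian_targets(
        targets, model.config.input_size, model.config.heatmap_stride,
        model.config.heatmap_sigma,
    )
    val = _stack(val_dataset) if val_dataset else None
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    wing = config.wing

    history: List[dict] = []

    def record(epoch: int, train_loss: float) -> None:
        val_loss = (
            _eval_loss(model, val[0], val[1], wing, config.batch_size) if val else float("nan")
        )
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        logger.info("epoch %d: train %.4f val %.4f", epoch, train_loss, val_loss)

    record(0, _eval_loss(model, images, targets, wing, config.batch_size))
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(images))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            optimizer.zero_grad()
            loss = _batch_loss(model, images[idx], targets[idx], hm_targets[idx],
                               wing, config.heatmap_aux_weight)
            loss.backward()
            optimizer.step()
            batch_losses.append(float(loss.data))
        record(epoch, float(np.mean(batch_losses)))

    if log_path is not None:
        Path(log_path).parent.mkdir(parents=True, exist_ok=True)
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
            writer.writeheader()
            writer.writerows(history)
    return history
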