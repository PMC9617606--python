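"""Model construction, training loop, and single-cube prediction.

Training minimizes the mean absolute error between the network output and
the target subtomograms with Adam (initial learning rate 4e-4).  One call to
:func:`train` performs the fixed number of epochs of one refinement
iteration; each epoch traverses the full paired dataset in shuffled batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, UNet3D
from .sampling import TrainingPair

__all__ = ["UNetConfig", "TrainConfig", "build_model", "train", "predict_cube"]


@dataclass
class UNetConfig:
    """depth encoder blocks; channel width doubles after each block."""

    depth: int = 3
    base_channels: int = 32
    convs_per_block: int = 3
    dropout_rate: float = 0.5
    rng_seed: int = 0


@dataclass
class TrainConfig:
    learning_rate: float = 4e-4
    epochs_per_iteration: int = 10
    batch_size: int = 8
    rng_seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def build_model(cfg: UNetConfig) -> UNet3D:
    """Build a randomly initialized U-Net; same seed => identical weights."""
    return UNet3D(depth=cfg.depth, base_channels=cfg.base_channels,
                  convs_per_block=cfg.convs_per_block,
                  dropout_rate=cfg.dropout_rate, rng_seed=cfg.rng_seed)


def _stack(pairs):
    x = np.stack([p.input for p in pairs])[..., None].astype(np.float32)
    t = np.stack([p.target for p in pairs])[..., None].astype(np.float32)
    return x, t


def train(model: UNet3D, pairs: list[TrainingPair], cfg: TrainConfig,
          optimizer: Adam | None = None):
    """Train in place; returns (model, per-epoch mean MAE list).

    Pass an existing optimizer to carry Adam moments across calls; by default
    a fresh optimizer is created (weights persist across refinement
    iterations, optimizer state does not).
    """
    if not pairs:
        raise ValueError("empty training set")
    x, t = _stack(pairs)
    opt = optimizer or Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.rng_seed)
    n = len(pairs)
    losses = []
    for _ in range(cfg.epochs_per_iteration):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, tb = x[idx], t[idx]
            y = model.forward(xb, train=True, rng=rng)
            diff = y - tb
            loss = float(np.abs(diff).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {len(losses) + 1}, "
                    f"batch {lo // cfg.batch_size}: {loss}"
                )
            model.zero_grad()
            model.backward(np.sign(diff).astype(np.float32) / diff.size)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        losses.append(total / seen)
    return model, losses


def predict_cube(model: UNet3D, cube: np.ndarray) -> np.ndarray:
    """Deterministic inference on one cube (dropout off)."""
    return model.predict(np.asarray(cube, dtype=np.float32))
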