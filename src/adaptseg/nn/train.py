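"""Training loop: Adam optimizer, per-epoch loss history, checkpoints.

Defaults mirror the clinical profile (learning rate 5e-4, Adam, batch size
1, 250 epochs for the localization step and 200 for the ROI step, dual
cross entropy); desk-scale runs pass smaller epoch counts through the same
configuration object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autodiff import DTYPE, Var
from .densenet import FCDenseNet3D
from .losses import dice_loss, dual_cross_entropy, sigmoid_bce


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    learning_rate: float = 5e-4
    optimizer: str = "adam"
    epochs_step1: int = 250
    epochs_step2: int = 200
    batch_size: int = 1
    loss: str = "dual_cross_entropy"  # | "cross_entropy" | "dice"
    fp_weight: float = 1.0
    eps: float = 1e-7
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs_step1 < 0 or self.epochs_step2 < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("dual_cross_entropy", "cross_entropy", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


class Adam:
    """Adaptive-moment estimation over a named parameter dict."""

    def __init__(self, params: Dict[str, Var], lr: float = 5e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= DTYPE(self.lr) * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _loss_fn(config: TrainConfig, net: FCDenseNet3D):
    if net.config.mode == "multilabel":
        def fn(scores, target):
            return sigmoid_bce(scores, target, eps=config.eps)
        return fn
    if config.loss == "dice":
        return lambda scores, target: dice_loss(scores, target)
    weight = 0.0 if config.loss == "cross_entropy" else config.fp_weight
    return lambda scores, target: dual_cross_entropy(scores, target, fp_weight=weight,
                                                     eps=config.eps)


def train(network: FCDenseNet3D, samples: Sequence[Tuple[np.ndarray, np.ndarray]],
          config: TrainConfig, epochs: Optional[int] = None,
          checkpoint_dir=None) -> Tuple[FCDenseNet3D, List[float]]:
    """Optimize ``network`` in place on ``samples``; returns it with the
    per-epoch mean-loss history.

    ``samples`` is a list of (input volume, target labels); inputs are
    (X, Y, Z) or (C, X, Y, Z) float arrays, targets integer label grids
    (single-label mode) or per-channel binary grids (multilabel mode).
    ``epochs=0`` returns the network unchanged with an empty history.
    Training twice from the same initial weights, data and seed replays the
    identical loss history.  A non-finite loss aborts with the epoch named.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    n_epochs = config.epochs_step1 if epochs is None else int(epochs)
    history: List[float] = []
    if n_epochs == 0:
        return network, history

    rng = np.random.default_rng(config.seed)
    opt = Adam(network.parameters(), lr=config.learning_rate)
    loss_fn = _loss_fn(config, network)
    best = np.inf
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)

    order = np.arange(len(samples))
    for epoch in range(n_epochs):
        if config.shuffle:
            rng.shuffle(order)
        losses = []
        for idx in order:
            x, target = samples[idx]
            opt.zero_grad()
            scores = network.forward(x)
            loss = loss_fn(scores, target)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, sample {idx}")
            loss.backward()
            opt.step()
            losses.append(value)
        mean_loss = float(np.mean(losses))
        history.append(mean_loss)
        if ckpt is not None and mean_loss < best:
            best = mean_loss
            network.save(ckpt / "best.npz")
    if ckpt is not None:
        network.save(ckpt / "last.npz")
        pd.DataFrame({"epoch": np.arange(len(history)), "loss": history}).to_csv(
            ckpt / "train_log.csv", index=False)
    return network, history
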