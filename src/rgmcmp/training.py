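"""Training protocol shared by every network variant.

Weights are he_normal-initialized from the run seed, optimized with Adam
at an initial learning rate of 2e-4 and batch size 1. The validation loss
is computed once per epoch; when it fails to improve on the best value
for ``lr_patience`` (30) consecutive epochs the learning rate is
multiplied by ``lr_factor`` (0.2), and when it fails to improve for
``stop_patience`` (50) consecutive epochs training stops. The returned
model carries the parameters of the epoch with the smallest validation
loss. Both patience counters run from the same best-epoch reference, and
the LR reduction can fire repeatedly. Improvement means a strict decrease
of the best-so-far value (tolerance 0). Training order is reshuffled every
epoch from the run seed; there is no augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network
from .objective import LossConfig, total_loss

__all__ = ["TrainConfig", "History", "Adam", "train"]


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    initial_lr: float = 2e-4
    batch_size: int = 1
    lr_patience: int = 30
    lr_factor: float = 0.2
    stop_patience: int = 50
    max_epochs: int = 1000
    seed: int = 0
    optimizer: str = "adam"
    init_scheme: str = "he_normal"

    def __post_init__(self) -> None:
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.stop_patience < self.lr_patience:
            raise ValueError("stop_patience must be ≥ lr_patience")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    stopped_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class Adam:
    """Adam with bias correction; state per parameter tensor."""

    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _epoch_loss(net: Network, dataset, loss_cfg: LossConfig) -> float:
    total = 0.0
    for x, y in dataset:
        p = net.forward(x)
        total += float(total_loss(p.data.astype(np.float64), y, loss_cfg))
    return total / len(dataset)


def train(
    net: Network,
    train_set,
    val_set,
    loss_cfg: LossConfig | None = None,
    cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> tuple[Network, History]:
    """Train ``net`` in place; returns (net at best validation loss, History).

    ``train_set`` and ``val_set`` are sequences of (input_array, label_mask)
    pairs; inputs are (C, X, Y, Z) float arrays, labels binary (X, Y, Z).
    """
    loss_cfg = loss_cfg or LossConfig()
    cfg = cfg or TrainConfig()
    if not len(train_set) or not len(val_set):
        raise TrainingError("training and validation sets must be nonempty")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, cfg.initial_lr)
    hist = History()
    best_state = net.state_dict()
    lr_wait = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        running = 0.0
        for idx in order:
            x, y = train_set[idx]
            net.zero_grad()
            p = net.forward(x)
            loss = total_loss(p, y, loss_cfg)
            lv = loss.item()
            if not np.isfinite(lv):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            running += lv
        train_loss = running / len(train_set)
        val_loss = _epoch_loss(net, val_set, loss_cfg)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        hist.train_loss.append(train_loss)
        hist.val_loss.append(val_loss)
        hist.lr.append(opt.lr)
        if verbose:
            print(f"epoch {epoch:4d}  train {train_loss:.4f}  val {val_loss:.4f}  lr {opt.lr:.2e}")

        if val_loss < hist.best_val_loss:
            hist.best_val_loss = val_loss
            hist.best_epoch = epoch
            best_state = net.state_dict()
            lr_wait = 0
        else:
            wait = epoch - hist.best_epoch
            lr_wait += 1
            if lr_wait >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                lr_wait = 0
            if wait >= cfg.stop_patience:
                hist.stopped_epoch = epoch
                break

    net.load_state_dict(best_state)
    return net, hist
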