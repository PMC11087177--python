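"""Training objective: cross-entropy, soft Dice and their combination.

With per-voxel class probabilities p_{i,k} and one-hot labels y_{i,k}
(N voxels, K classes):

    L_ce   = (1/N) Σ_i Σ_k −y_{i,k} log p_{i,k}
    L_dice = 1 − (1/K) Σ_k (2 Σ_i p_{i,k} y_{i,k} + ε) / (Σ_i p_{i,k} + Σ_i y_{i,k} + ε)
    L      = w_ce · L_ce + w_dice · L_dice          (default weights 0.5 / 0.5)

ε (default 1) keeps the Dice ratio defined — an all-empty class scores a
perfect 1 rather than 0/0. Probabilities are clipped to
[prob_floor, 1] inside the logarithm so L_ce is finite at p = 0. K counts
the background class, so the Dice average runs over both classes.

Every function accepts either plain numpy arrays (returning a float) or
autodiff :class:`~rgmcmp.nn.autodiff.Tensor` probabilities (returning a
Tensor through which gradients flow), so the same code defines both the
reported metric and the training objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = ["LossConfig", "cross_entropy_loss", "dice_loss", "total_loss", "one_hot"]


@dataclass
class LossConfig:
    epsilon: float = 1.0
    weights: tuple[float, float] = (0.5, 0.5)  # (w_ce, w_dice)
    prob_floor: float = 1e-7

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if any(w < 0 for w in self.weights):
            raise ValueError("loss weights must be nonnegative")


def one_hot(mask: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Binary mask (X,Y,Z) -> one-hot (K,X,Y,Z); a (K,...) input passes through."""
    m = np.asarray(mask)
    if m.ndim == 4:
        return m.astype(np.float32)
    out = np.zeros((n_classes, *m.shape), dtype=np.float32)
    for k in range(n_classes):
        out[k] = m == k
    return out


def _check(p, y) -> tuple[Tensor | np.ndarray, np.ndarray, bool]:
    is_tensor = isinstance(p, Tensor)
    p_data = p.data if is_tensor else np.asarray(p, dtype=np.float64)
    y = one_hot(y, n_classes=p_data.shape[0])
    if p_data.shape != y.shape:
        raise ValueError(f"probability/label shape mismatch: {p_data.shape} vs {y.shape}")
    return p, y, is_tensor


def cross_entropy_loss(p, y, cfg: LossConfig | None = None):
    cfg = cfg or LossConfig()
    p, y, is_tensor = _check(p, y)
    n = float(np.prod(y.shape[1:]))
    if is_tensor:
        logp = ad.log(ad.clip(p, cfg.prob_floor, 1.0))
        return ad.mul(ad.sum_all(ad.mul(logp, Tensor(y))), -1.0 / n)
    pc = np.clip(p, cfg.prob_floor, 1.0)
    return float(-(y * np.log(pc)).sum() / n)


def dice_loss(p, y, cfg: LossConfig | None = None):
    cfg = cfg or LossConfig()
    p, y, is_tensor = _check(p, y)
    k = y.shape[0]
    eps = cfg.epsilon
    if is_tensor:
        total = Tensor(0.0)
        for c in range(k):
            yc = Tensor(y[c])
            pc = _slice_channel(p, c)
            inter = ad.sum_all(ad.mul(pc, yc))
            denom = ad.add(ad.add(ad.sum_all(pc), float(y[c].sum())), eps)
            ratio = _divide(ad.add(ad.mul(inter, 2.0), eps), denom)
            total = ad.add(total, ratio)
        return ad.add(1.0, ad.mul(total, -1.0 / k))
    ratios = [
        (2.0 * (p[c] * y[c]).sum() + eps) / (p[c].sum() + y[c].sum() + eps)
        for c in range(k)
    ]
    return float(1.0 - np.mean(ratios))


def total_loss(p, y, cfg: LossConfig | None = None):
    cfg = cfg or LossConfig()
    w_ce, w_dice = cfg.weights
    ce = cross_entropy_loss(p, y, cfg)
    dl = dice_loss(p, y, cfg)
    if isinstance(ce, Tensor):
        return ad.add(ad.mul(ce, w_ce), ad.mul(dl, w_dice))
    return float(w_ce * ce + w_dice * dl)


# -- small Tensor helpers ----------------------------------------------------

def _slice_channel(p: Tensor, c: int) -> Tensor:
    out = Tensor(p.data[c], parents=(p,))

    def backward(g):
        if p.requires_grad:
            full = np.zeros_like(p.data)
            full[c] = g
            p._accumulate(full)

    out._backward = backward
    return out


def _divide(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / b.data)
        if b.requires_grad:
            b._accumulate(-g * a.data / b.data**2)

    out._backward = backward
    return out
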