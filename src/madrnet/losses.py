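"""Segmentation losses: cross-entropy, dice, focal Tversky, and their hybrid.

All losses accept a prediction ``p`` (probabilities in [0, 1], shape
(N, M, H, W); M = 1 for binary tasks) and a target ``q`` of the same shape
(binary / one-hot), as either NumPy arrays or autograd tensors, and return a
scalar :class:`~madrnet.autograd.Tensor` so they can drive training
directly.

The focal Tversky loss generalizes dice with asymmetric false-positive /
false-negative weights ``alpha`` and ``beta`` and a focusing exponent
``1/gamma``: per class m,

    TI_m = sum(p0*q0) / (sum(p0*q0) + alpha*sum(p0*q1) + beta*sum(p1*q0))
    loss = sum_m (1 - TI_m)**(1/gamma)

where p0/p1 are foreground/background probabilities and q0/q1 the target
indicator pair.  With alpha = beta = 0.5 and gamma = 1 it reduces to the
(unsmoothed) dice loss per class.  Defaults alpha = 0.7, beta = 0.3 weight
false negatives more heavily (recall-oriented), and gamma = 1.33 focuses
training on hard, small regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

EPS = 1e-7


@dataclass
class LossConfig:
    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 1.33
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (ce, dice, ft)
    mode: str = "binary"  # binary | multiclass
    dice_smooth: float = 1.0

    def __post_init__(self):
        self.weights = tuple(float(w) for w in self.weights)
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.mode not in ("binary", "multiclass"):
            raise ValueError("mode must be 'binary' or 'multiclass'")
        if any(w < 0 for w in self.weights):
            raise ValueError("loss weights must be non-negative")
        if not any(w > 0 for w in self.weights):
            raise ValueError("at least one loss weight must be positive")


def _pair(p, q) -> tuple[Tensor, np.ndarray]:
    p = ag.as_tensor(p)
    q = q.data if isinstance(q, Tensor) else np.asarray(q, dtype=p.dtype)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {q.shape}")
    if p.size == 0:
        raise ValueError("empty prediction/target")
    return p, q


def bce_loss(p, q) -> Tensor:
    """Binary cross-entropy, averaged over all output elements."""
    p, q = _pair(p, q)
    pc = ag.clip(p, EPS, 1.0 - EPS)
    ll = Tensor(q) * ag.log(pc) + Tensor(1.0 - q) * ag.log(1.0 - pc)
    return -ll.mean()


def cce_loss(p, q) -> Tensor:
    """Categorical cross-entropy, averaged over pixels (not classes)."""
    p, q = _pair(p, q)
    if p.shape[1] < 2:
        raise ValueError("cce_loss expects at least two class channels")
    csum = q.sum(axis=1)
    if not (np.isin(q, (0.0, 1.0)).all() and np.allclose(csum, 1.0)):
        raise ValueError("target must be one-hot over the class axis")
    pc = ag.clip(p, EPS, 1.0 - EPS)
    n_pixels = p.size // p.shape[1]
    return -(Tensor(q) * ag.log(pc)).sum() / n_pixels


def dice_loss(p, q, smooth: float = 1.0) -> Tensor:
    """Soft dice loss ``1 - (2*sum(pq) + s) / (sum(p) + sum(q) + s)``.

    With ``smooth=0`` on hard masks this is exactly one minus the dice
    similarity coefficient; ``smooth=1`` (default) keeps the loss defined
    and differentiable on empty masks.
    """
    p, q = _pair(p, q)
    inter = (p * Tensor(q)).sum()
    denom = p.sum() + float(q.sum())
    if smooth == 0 and denom.item() == 0 and inter.item() == 0:
        return Tensor(0.0)  # both empty: perfect agreement
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def focal_tversky_loss(p, q, cfg: LossConfig = LossConfig()) -> Tensor:
    """Focal Tversky loss summed over the M class channels."""
    p, q = _pair(p, q)
    if cfg.gamma <= 0:
        raise ValueError("gamma must be positive")
    M = p.shape[1]
    total = None
    for m in range(M):
        p0 = _channel(p, m)
        q0 = q[:, m]
        tp = (p0 * Tensor(q0)).sum()
        fp = (p0 * Tensor(1.0 - q0)).sum()
        fn = ((1.0 - p0) * Tensor(q0)).sum()
        denom = tp + cfg.alpha * fp + cfg.beta * fn
        if denom.item() == 0:
            # class absent and never predicted: a perfect class term
            term = Tensor(0.0)
        else:
            ti = tp / denom
            term = (1.0 - ti) ** (1.0 / cfg.gamma)
        total = term if total is None else total + term
    return total


def _channel(p: Tensor, m: int) -> Tensor:
    """Differentiable slice of class channel ``m``."""
    data = p.data[:, m]

    def backward(grad):
        if p.requires_grad:
            g = np.zeros_like(p.data)
            g[:, m] = grad
            p._accumulate(g)

    return ag._make(data, (p,), backward)


def hybrid_loss(p, q, cfg: LossConfig = LossConfig()) -> Tensor:
    """Weighted sum of cross-entropy, dice, and focal Tversky losses."""
    w_ce, w_dice, w_ft = cfg.weights
    if w_ce == w_dice == w_ft == 0:
        raise ValueError("all hybrid weights are zero")
    total = Tensor(0.0)
    if w_ce:
        ce = bce_loss(p, q) if cfg.mode == "binary" else cce_loss(p, q)
        total = total + w_ce * ce
    if w_dice:
        total = total + w_dice * dice_loss(p, q, smooth=cfg.dice_smooth)
    if w_ft:
        total = total + w_ft * focal_tversky_loss(p, q, cfg)
    return total


def hybrid_components(p, q, cfg: LossConfig = LossConfig()) -> dict[str, float]:
    """The three unweighted loss components, for logging."""
    ce = bce_loss(p, q) if cfg.mode == "binary" else cce_loss(p, q)
    return {
        "ce": ce.item(),
        "dice": dice_loss(p, q, smooth=cfg.dice_smooth).item(),
        "focal_tversky": focal_tversky_loss(p, q, cfg).item(),
    }
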