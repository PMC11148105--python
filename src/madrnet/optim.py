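"""Optimizers and learning-rate scheduling."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the standard defaults (Kingma & Ba)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = p.data - self.lr * update.astype(p.data.dtype)

    def state_dict(self) -> dict:
        return {"t": self.t, "lr": self.lr, "m": self._m, "v": self._v}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self._m = [np.asarray(m) for m in state["m"]]
        self._v = [np.asarray(v) for v in state["v"]]


class ReduceLROnPlateau:
    """Halve the learning rate when a monitored value stops improving.

    Mirrors the usual reduce-on-plateau policy: ``mode='max'`` treats larger
    monitored values (e.g. validation dice) as better.
    """

    def __init__(self, optimizer: Adam, mode: str = "max", factor: float = 0.5,
                 patience: int = 20, min_lr: float = 1e-6):
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.optimizer = optimizer
        self.mode = mode
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best: float | None = None
        self.bad_epochs = 0

    def step(self, value: float) -> bool:
        """Record one epoch's monitored value; returns True if lr was reduced."""
        improved = (
            self.best is None
            or (self.mode == "max" and value > self.best)
            or (self.mode == "min" and value < self.best)
        )
        if improved:
            self.best = value
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
            reduced = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            self.bad_epochs = 0
            return reduced
        return False
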