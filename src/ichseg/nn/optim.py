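"""Adam optimizer with per-epoch exponential learning-rate decay.

Matches the schedule used throughout the study: Adam with its canonical
defaults (beta1=0.9, beta2=0.999, eps=1e-8), initial learning rate 1e-3
decayed by a factor 0.96 each epoch, and a decoupled L2 penalty of 1e-6
added to the gradient as ``l2 * w``.
"""

from __future__ import annotations

import numpy as np

from .network import Module

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        module: Module,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        l2: float = 1e-6,
        lr_decay_base: float = 0.96,
        frozen_prefixes: tuple[str, ...] = (),
    ):
        self.module = module
        self.lr0 = lr
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.l2 = l2
        self.lr_decay_base = lr_decay_base
        self.frozen_prefixes = tuple(frozen_prefixes)
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def set_epoch(self, epoch: int) -> None:
        """Exponential decay: lr = lr0 * base**epoch (epoch 0 = no decay)."""
        self.lr = self.lr0 * self.lr_decay_base**epoch

    def _is_frozen(self, name: str) -> bool:
        return any(name.startswith(p) for p in self.frozen_prefixes)

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        params = self.module.named_parameters()
        grads = self.module.named_gradients()
        for name, w in params.items():
            if name not in grads or self._is_frozen(name):
                continue
            g = grads[name].astype(np.float32) + self.l2 * w
            if name not in self.m:
                self.m[name] = np.zeros_like(w)
                self.v[name] = np.zeros_like(w)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / bc1
            vhat = self.v[name] / bc2
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
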