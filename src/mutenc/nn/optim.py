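"""AdamW, gradient clipping and learning-rate schedules."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Decoupled weight decay Adam (betas (0.9, 0.999), eps 1e-8 defaults)."""

    def __init__(
        self,
        params,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update


def global_grad_norm(params) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad**2))
    return float(np.sqrt(total))


def clip_grad_norm_(params, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``.

    Returns the pre-clipping norm.
    """
    params = list(params)
    norm = global_grad_norm(params)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


def lr_at_step(
    step: int,
    total_steps: int,
    base_lr: float,
    warmup_frac: float,
    cosine_decay: bool = False,
) -> float:
    """Closed-form schedule: linear warmup from 0, then constant or cosine to 0.

    ``step`` counts from 0; the warmup period spans ``round(warmup_frac *
    total_steps)`` steps (at least 1), peaking at ``base_lr`` at its end.  With
    ``cosine_decay`` the rate then follows half a cosine down to 0 at the
    final step.
    """
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return base_lr * step / warmup
    if not cosine_decay:
        return base_lr
    last = max(total_steps - 1, warmup)
    if last == warmup:
        return base_lr
    frac = (step - warmup) / (last - warmup)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))
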