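"""Optimizers: Adam, and a differentially private Adam step built from
per-example clipped and noised gradients."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray] | None = None) -> None:
        """Apply one update from ``grads`` (or from each param's .grad)."""
        self.t += 1
        for i, p in enumerate(self.params):
            g = grads[i] if grads is not None else p.grad
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_global_norm(grads: list[np.ndarray], clip_norm: float) -> list[np.ndarray]:
    """Rescale one example's gradient list so its global L2 norm is <= C."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total <= clip_norm or total == 0.0:
        return [g.copy() for g in grads]
    scale = clip_norm / total
    return [g * scale for g in grads]


def dp_aggregate(per_example_grads: list[list[np.ndarray]], clip_norm: float,
                 noise_multiplier: float, rng: np.random.Generator,
                 denominator: int | None = None) -> list[np.ndarray]:
    """DP-SGD gradient aggregation: clip each example to ``clip_norm``,
    sum, add N(0, (noise_multiplier * clip_norm)^2) noise per coordinate,
    and divide by the (expected) batch size."""
    if not per_example_grads:
        raise ValueError("dp_aggregate needs at least one example gradient")
    n = denominator if denominator is not None else len(per_example_grads)
    clipped = [clip_global_norm(g, clip_norm) for g in per_example_grads]
    out = []
    for i in range(len(clipped[0])):
        total = np.sum([c[i] for c in clipped], axis=0)
        noise = rng.normal(0.0, noise_multiplier * clip_norm, size=total.shape)
        out.append((total + noise) / n)
    return out
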