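"""Neural layers built on the autodiff core: dense, LSTM, 1-D
convolution (im2col), max pooling, layer norm and multi-head attention.

All layers expose ``parameters()`` and are initialized from an explicit
``numpy.random.Generator`` so whole models are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, exp, relu, sigmoid, stack, tanh


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.data.shape)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LSTM(Module):
    """Single LSTM layer; input (N, T, n_in) → hidden sequence (N, T, H).

    Gate order in the fused weight matrix: input, forget, cell, output.
    The forget-gate bias starts at 1 (standard stabilization).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        fused = n_in + n_hidden
        self.W = Tensor(
            _glorot(rng, fused, 4 * n_hidden, (fused, 4 * n_hidden)),
            requires_grad=True,
        )
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, return_sequence: bool = True) -> Tensor:
        N, T, _ = x.shape
        H = self.n_hidden
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        outputs: list[Tensor] = []
        for t in range(T):
            xt = x[:, t, :]
            z = concat([xt, h], axis=1) @ self.W + self.b
            i = sigmoid(z[:, 0:H])
            f = sigmoid(z[:, H : 2 * H])
            g = tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * tanh(c)
            outputs.append(h)
        if return_sequence:
            return stack(outputs, axis=1)
        return outputs[-1]


class Conv1d(Module):
    """1-D convolution over the last axis with zero 'same' padding.

    Input (N, C_in, L) → (N, C_out, L); implemented as im2col + matmul
    so the backward pass falls out of the generic indexing gradient.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        self.W = Tensor(
            _glorot(rng, fan_in, c_out, (fan_in, c_out)), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        N, C, L = x.shape
        K = self.kernel
        pad_l = (K - 1) // 2
        pad_r = K - 1 - pad_l
        xp = _zero_pad_last(x, pad_l, pad_r)
        idx = np.arange(L)[:, None] + np.arange(K)[None, :]  # (L, K)
        cols = xp[:, :, idx]                                  # (N, C, L, K)
        cols = cols.transpose(0, 2, 1, 3).reshape(N, L, C * K)
        out = cols @ self.W + self.b                          # (N, L, C_out)
        return out.transpose(0, 2, 1)


def _zero_pad_last(x: Tensor, left: int, right: int) -> Tensor:
    if left == 0 and right == 0:
        return x
    shape = x.shape[:-1] + (x.shape[-1] + left + right,)
    padded = Tensor(np.zeros(shape))
    # route x into the middle via the indexing gradient
    out_data = padded.data.copy()
    out_data[..., left : left + x.shape[-1]] = x.data
    out = Tensor(out_data, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g[..., left : left + x.shape[-1]])

    out._backward = bwd
    return out


def max_pool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling over the last axis (trailing remainder
    dropped)."""
    N, C, L = x.shape
    L2 = (L // size) * size
    trimmed = x[:, :, :L2] if L2 != L else x
    return trimmed.reshape(N, C, L2 // size, size).max(axis=3)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        norm = centered * (var + self.eps).pow(-0.5)
        return norm * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Self-attention over a short token sequence (N, S, D)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.dim = dim
        self.q = Dense(dim, dim, rng)
        self.k = Dense(dim, dim, rng)
        self.v = Dense(dim, dim, rng)
        self.out = Dense(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        N, S, D = x.shape
        H, Dh = self.n_heads, D // self.n_heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(N, S, H, Dh).transpose(0, 2, 1, 3)  # (N, H, S, Dh)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Dh))
        attn = softmax(scores, axis=-1)
        ctx = attn @ v  # (N, H, S, Dh)
        merged = ctx.transpose(0, 2, 1, 3).reshape(N, S, D)
        return self.out(merged)


def binary_cross_entropy(p: Tensor, targets: np.ndarray,
                         weights: np.ndarray | None = None,
                         eps: float = 1e-7) -> Tensor:
    """Mean BCE of probabilities ``p`` against 0/1 ``targets``.

    Probabilities are shrunk into [eps, 1-eps] inside the graph so the
    loss and its gradient stay finite at saturation.
    """
    t = np.asarray(targets, dtype=float).reshape(p.shape)
    p_safe = p * (1.0 - 2.0 * eps) + eps
    from .autodiff import log as _log

    losses = -(Tensor(t) * _log(p_safe) + Tensor(1.0 - t) * _log(1.0 - p_safe))
    if weights is not None:
        w = np.asarray(weights, dtype=float).reshape(p.shape)
        losses = losses * Tensor(w)
    return losses.mean()
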