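"""Binary stress classifiers over 6 × 210 averaged spectra.

Three architectures, all trained with Adam on a weighted binary
cross-entropy (inverse-class-frequency weights, normalized to mean 1):

* ``CnnClassifier`` — three 1-D convolution blocks over the frequency
  axis (widths 32/64/128, kernel 5, max-pool 2) + dense head;
* ``CnnLstmClassifier`` — the same convolutional trunk with two LSTM
  layers (128, 64) between the convolutions and the dense head;
* ``TsctClassifier`` — a small transformer encoder treating the six
  signal spectra as a 6-token sequence (width 64, 4 heads, 2 blocks).

Each can train privately: with a ``PrivacySpec`` the optimizer switches
to DP-Adam (per-example clipped, Gaussian-noised gradients with noise
calibrated to the requested ε).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import dp as dp_mod
from .nn import (
    LSTM,
    Adam,
    Conv1d,
    Dense,
    LayerNorm,
    Module,
    MultiHeadAttention,
    Tensor,
    binary_cross_entropy,
    max_pool1d,
    relu,
    sigmoid,
)
from .nn.optim import clip_global_norm
from .spectra import SpectrumSet

__all__ = [
    "Metrics", "ClassifierError", "CnnClassifier", "CnnLstmClassifier",
    "TsctClassifier", "make_classifier", "train_classifier", "evaluate",
    "compute_metrics",
]


class ClassifierError(ValueError):
    pass


@dataclass
class Metrics:
    """Precision / recall / F1 / accuracy plus the confusion counts.

    Degenerate denominators (no positive predictions, or no positive
    truths) yield 0 for the affected metric, with the flag recorded.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    flags: list[str] = field(default_factory=list)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    flags = []
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, flags = 0.0, flags + ["no_positive_predictions"]
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, flags = 0.0, flags + ["no_positive_truths"]
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    accuracy = (tp + tn) / max(1, len(y_true))
    return Metrics(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                   recall=recall, f1=f1, accuracy=accuracy, flags=flags)


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Per-example inverse-class-frequency weights, normalized to mean 1."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    w = np.empty(n, dtype=float)
    for lab in (0, 1):
        mask = y == lab
        if mask.any():
            w[mask] = n / (2.0 * mask.sum())
    return w / w.mean()


class _BaseNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared training loop: validation, standardization, Adam / DP-Adam,
    seeded batching, 0.5-threshold prediction."""

    def __init__(self, epochs: int, batch_size: int = 50,
                 learning_rate: float = 1e-3, class_weight: str = "balanced",
                 privacy: dp_mod.PrivacySpec | None = None,
                 random_state: int | None = None):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.class_weight = class_weight
        self.privacy = privacy
        self.random_state = random_state

    # subclasses build the network
    def _build(self, rng: np.random.Generator) -> Module:  # pragma: no cover
        raise NotImplementedError

    def _forward(self, X: np.ndarray) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y=None):
        if isinstance(X, SpectrumSet):
            X, y = X.features, X.labels
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ClassifierError(f"expected (N, 6, 210) spectra, got {X.shape}")
        if len(np.unique(y)) < 2:
            raise ClassifierError("training requires both classes")
        rng = np.random.default_rng(self.random_state)
        # per-feature standardization keeps the magnitudes of different
        # spectral bins comparable for the small networks
        self.mu_ = X.mean(axis=0)
        self.sd_ = np.maximum(X.std(axis=0), 1e-8)
        Xn = (X - self.mu_) / self.sd_
        self.net_ = self._build(rng)
        self.classes_ = np.array([0, 1])
        weights = (_class_weights(y) if self.class_weight == "balanced"
                   else np.ones(len(y)))

        private = self.privacy is not None and self.privacy.is_private
        if private:
            spec = self.privacy
            unique_n = spec.unique_n if spec.unique_n is not None else len(X)
            eff = (spec.effective_epochs if spec.effective_epochs is not None
                   else max(1, self.epochs))
            calib = dp_mod.PrivacySpec(
                epsilon=spec.epsilon, delta=spec.delta, clip_norm=spec.clip_norm,
                batch_size=spec.batch_size, unique_n=unique_n,
                effective_epochs=eff, learning_rate=spec.learning_rate)
            self.noise_multiplier_ = (spec.noise_multiplier
                                      if spec.noise_multiplier is not None
                                      else dp_mod.calibrate_noise(calib))
            self.accountant_ = dp_mod.AccountantState(
                sigma=self.noise_multiplier_, q=calib.sampling_rate,
                delta=spec.delta)
            batch = spec.batch_size
            lr = spec.learning_rate
        else:
            if self.privacy is not None:  # ε = ∞ passthrough
                import logging
                logging.getLogger(__name__).info(
                    "privacy spec with epsilon=inf: training non-privately")
            self.noise_multiplier_ = 0.0
            self.accountant_ = None
            batch = self.batch_size
            lr = self.learning_rate

        opt = Adam(self.net_.parameters(), lr=lr)
        n = len(Xn)
        self.loss_trace_ = []
        for _epoch in range(self.epochs):
            losses = []
            if private:
                steps = max(1, n // batch)
                batches = [np.flatnonzero(rng.random(n) < self.accountant_.q)
                           for _ in range(steps)]
                batches = [b for b in batches if b.size]
            else:
                order = rng.permutation(n)
                steps = max(1, math.ceil(n / batch))
                batches = [order[i * batch : (i + 1) * batch]
                           for i in range(steps)]
                batches = [b for b in batches if b.size]
            for idx in batches:
                if private:
                    loss_val = self._dp_step(opt, Xn[idx], y[idx], weights[idx], rng)
                    self.accountant_.step()
                else:
                    self.net_.zero_grad()
                    p = self._forward(Xn[idx])
                    loss = binary_cross_entropy(p, y[idx], weights[idx])
                    loss.backward()
                    opt.step()
                    loss_val = float(loss.data)
                if not math.isfinite(loss_val):
                    raise RuntimeError(f"non-finite loss at epoch {_epoch}")
                losses.append(loss_val)
            self.loss_trace_.append(float(np.mean(losses)) if losses else math.nan)
        return self

    def _dp_step(self, opt: Adam, Xb, yb, wb, rng) -> float:
        spec = self.privacy
        params = self.net_.parameters()
        per_example, losses = [], []
        for i in range(len(Xb)):
            self.net_.zero_grad()
            p = self._forward(Xb[i : i + 1])
            loss = binary_cross_entropy(p, yb[i : i + 1], wb[i : i + 1])
            loss.backward()
            grads = [pr.grad.copy() if pr.grad is not None else np.zeros_like(pr.data)
                     for pr in params]
            per_example.append(clip_global_norm(grads, spec.clip_norm))
            losses.append(float(loss.data))
        noisy = []
        for j in range(len(params)):
            total = np.sum([g[j] for g in per_example], axis=0)
            noise = rng.normal(0.0, self.noise_multiplier_ * spec.clip_norm,
                               size=total.shape)
            noisy.append((total + noise) / spec.batch_size)
        opt.step(grads=noisy)
        return float(np.mean(losses))

    def predict_proba(self, X):
        if isinstance(X, SpectrumSet):
            X = X.features
        X = np.asarray(X, dtype=float)
        Xn = (X - self.mu_) / self.sd_
        p1 = self._forward(Xn).data.reshape(-1)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class _ConvTrunk(Module):
    def __init__(self, c_in: int, widths, kernel: int, rng):
        self.blocks = [Conv1d(c_in if i == 0 else widths[i - 1], w, kernel, rng)
                       for i, w in enumerate(widths)]

    def __call__(self, x: Tensor) -> Tensor:
        for conv in self.blocks:
            x = max_pool1d(relu(conv(x)), 2)
        return x  # (N, widths[-1], L_out)


class _CnnNet(Module):
    def __init__(self, conv_widths, kernel, dense_width, rng):
        self.trunk = _ConvTrunk(6, conv_widths, kernel, rng)
        L_out = 210
        for _ in conv_widths:
            L_out //= 2
        self.dense = Dense(conv_widths[-1] * L_out, dense_width, rng)
        self.head = Dense(dense_width, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.trunk(x)
        N = h.shape[0]
        flat = h.reshape(N, -1)
        return sigmoid(self.head(relu(self.dense(flat))))


class _CnnLstmNet(Module):
    def __init__(self, conv_widths, kernel, lstm_widths, dense_width, rng):
        self.trunk = _ConvTrunk(6, conv_widths, kernel, rng)
        self.rnn1 = LSTM(conv_widths[-1], lstm_widths[0], rng)
        self.rnn2 = LSTM(lstm_widths[0], lstm_widths[1], rng)
        self.dense = Dense(lstm_widths[1], dense_width, rng)
        self.head = Dense(dense_width, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.trunk(x)                       # (N, C, L)
        seq = h.transpose(0, 2, 1)              # (N, L, C)
        last = self.rnn2(self.rnn1(seq), return_sequence=False)
        return sigmoid(self.head(relu(self.dense(last))))


class _TsctNet(Module):
    """Transformer encoder over the six per-signal spectra as tokens."""

    def __init__(self, model_dim, n_heads, n_blocks, ff_width, rng):
        self.embed = Dense(210, model_dim, rng)
        self.pos = Tensor(0.02 * rng.standard_normal((6, model_dim)),
                          requires_grad=True)
        self.attn = [MultiHeadAttention(model_dim, n_heads, rng)
                     for _ in range(n_blocks)]
        self.ln1 = [LayerNorm(model_dim) for _ in range(n_blocks)]
        self.ff1 = [Dense(model_dim, ff_width, rng) for _ in range(n_blocks)]
        self.ff2 = [Dense(ff_width, model_dim, rng) for _ in range(n_blocks)]
        self.ln2 = [LayerNorm(model_dim) for _ in range(n_blocks)]
        self.head = Dense(model_dim, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.embed(x) + self.pos
        for attn, ln1, ff1, ff2, ln2 in zip(self.attn, self.ln1, self.ff1,
                                            self.ff2, self.ln2):
            h = ln1(h + attn(h))
            h = ln2(h + ff2(relu(ff1(h))))
        pooled = h.mean(axis=1)
        return sigmoid(self.head(pooled))


class CnnClassifier(_BaseNetClassifier):
    def __init__(self, epochs: int = 10, batch_size: int = 50,
                 learning_rate: float = 1e-3, class_weight: str = "balanced",
                 conv_widths: tuple[int, ...] = (32, 64, 128), kernel: int = 5,
                 dense_width: int = 128,
                 privacy: dp_mod.PrivacySpec | None = None,
                 random_state: int | None = None):
        super().__init__(epochs, batch_size, learning_rate, class_weight,
                         privacy, random_state)
        self.conv_widths = conv_widths
        self.kernel = kernel
        self.dense_width = dense_width

    def _build(self, rng):
        return _CnnNet(tuple(self.conv_widths), self.kernel, self.dense_width, rng)

    def _forward(self, X):
        return self.net_(Tensor(X))


class CnnLstmClassifier(_BaseNetClassifier):
    def __init__(self, epochs: int = 20, batch_size: int = 50,
                 learning_rate: float = 1e-3, class_weight: str = "balanced",
                 conv_widths: tuple[int, ...] = (32, 64, 128), kernel: int = 5,
                 lstm_widths: tuple[int, int] = (128, 64), dense_width: int = 128,
                 privacy: dp_mod.PrivacySpec | None = None,
                 random_state: int | None = None):
        super().__init__(epochs, batch_size, learning_rate, class_weight,
                         privacy, random_state)
        self.conv_widths = conv_widths
        self.kernel = kernel
        self.lstm_widths = lstm_widths
        self.dense_width = dense_width

    def _build(self, rng):
        return _CnnLstmNet(tuple(self.conv_widths), self.kernel,
                           tuple(self.lstm_widths), self.dense_width, rng)

    def _forward(self, X):
        return self.net_(Tensor(X))


class TsctClassifier(_BaseNetClassifier):
    def __init__(self, epochs: int = 110, batch_size: int = 50,
                 learning_rate: float = 1e-3, class_weight: str = "balanced",
                 model_dim: int = 64, n_heads: int = 4, n_blocks: int = 2,
                 ff_width: int = 128,
                 privacy: dp_mod.PrivacySpec | None = None,
                 random_state: int | None = None):
        super().__init__(epochs, batch_size, learning_rate, class_weight,
                         privacy, random_state)
        self.model_dim = model_dim
        self.n_heads = n_heads
        self.n_blocks = n_blocks
        self.ff_width = ff_width

    def _build(self, rng):
        return _TsctNet(self.model_dim, self.n_heads, self.n_blocks,
                        self.ff_width, rng)

    def _forward(self, X):
        return self.net_(Tensor(X))


_KINDS = {"cnn": CnnClassifier, "cnn_lstm": CnnLstmClassifier,
          "tsct": TsctClassifier}


def make_classifier(kind: str, **params):
    if kind not in _KINDS:
        raise ClassifierError(
            f"unknown classifier kind {kind!r}; expected one of {sorted(_KINDS)}")
    return _KINDS[kind](**params)


def train_classifier(features: SpectrumSet, kind: str = "cnn", **params):
    """Functional wrapper: build and fit a classifier on a SpectrumSet."""
    est = make_classifier(kind, **params)
    return est.fit(features.features, features.labels)


def evaluate(model, features: SpectrumSet | np.ndarray,
             labels: np.ndarray | None = None) -> Metrics:
    """Hard predictions at the 0.5 threshold → confusion-based metrics."""
    if isinstance(features, SpectrumSet):
        X, y = features.features, features.labels
    else:
        X, y = np.asarray(features), np.asarray(labels)
    if len(X) == 0:
        raise ClassifierError("evaluate needs a non-empty feature set")
    return compute_metrics(y, model.predict(X))
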