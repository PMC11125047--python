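"""Conditional GAN over labeled 60-s multimodal windows.

The generator maps per-timestep Gaussian noise plus a broadcast one-hot
stress label through two stacked LSTM layers and a sigmoid head to a
60 × 6 window in [0, 1]; the discriminator stacks two LSTM layers over
the window (with the same label broadcast) and scores it real/fake.
Training minimizes the non-saturating adversarial loss, with the
generator loss extended by a diversity-sensitive term
−min(τ, ‖G(z₁) − G(z₂)‖ / ‖z₁ − z₂‖) that penalizes mode collapse, at
weight λ (default 8).

The private variant (DP-CGAN) switches only the discriminator to a
differentially private Adam — per-microbatch clipped, Gaussian-noised
gradients with Poisson batch sampling — because only the discriminator
touches real data; the generator keeps its ordinary optimizer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import dp as dp_mod
from .nn import (
    LSTM,
    Adam,
    Dense,
    Module,
    Tensor,
    binary_cross_entropy,
    concat,
    relu,
    sigmoid,
)
from .nn.optim import clip_global_norm
from .prep import WindowSet

__all__ = ["ConditionalGan", "SyntheticCohort", "GanError",
           "diversity_penalty", "synthesize_subjects", "train_cgan"]

WINDOW_S = 60
N_SIGNALS = 6


class GanError(ValueError):
    pass


def _one_hot(labels: np.ndarray, T: int = WINDOW_S) -> np.ndarray:
    """Binary label → per-timestep one-hot, shape (N, T, 2)."""
    labels = np.asarray(labels, dtype=int)
    eye = np.eye(2)[labels]  # (N, 2)
    return np.repeat(eye[:, None, :], T, axis=1)


class _Generator(Module):
    def __init__(self, noise_dim: int, widths: tuple[int, int],
                 rng: np.random.Generator):
        self.rnn1 = LSTM(noise_dim + 2, widths[0], rng)
        self.rnn2 = LSTM(widths[0], widths[1], rng)
        self.head = Dense(widths[1], N_SIGNALS, rng)

    def __call__(self, z: Tensor, onehot: np.ndarray) -> Tensor:
        x = concat([z, Tensor(onehot)], axis=2)
        h = self.rnn2(self.rnn1(x))
        N, T, W = h.shape
        flat = h.reshape(N * T, W)
        return sigmoid(self.head(flat)).reshape(N, T, N_SIGNALS)


class _Discriminator(Module):
    def __init__(self, widths: tuple[int, int], rng: np.random.Generator):
        self.rnn1 = LSTM(N_SIGNALS + 2, widths[0], rng)
        self.rnn2 = LSTM(widths[0], widths[1], rng)
        self.head = Dense(widths[1], 1, rng)

    def __call__(self, w: Tensor, onehot: np.ndarray) -> Tensor:
        x = concat([w, Tensor(onehot)], axis=2)
        h_last = self.rnn2(self.rnn1(x), return_sequence=False)
        return sigmoid(self.head(h_last))


def diversity_penalty(w1: np.ndarray, w2: np.ndarray, z1: np.ndarray,
                      z2: np.ndarray, tau: float = 1.0) -> float:
    """Bounded negative diversity ratio −min(τ, ‖w1−w2‖ / ‖z1−z2‖).

    Added to the generator loss (weighted by λ); more output spread per
    unit latent spread lowers the loss, capped at τ so the reward
    saturates.
    """
    dz = float(np.linalg.norm(np.asarray(z1) - np.asarray(z2)))
    if dz == 0.0:
        raise GanError("diversity ratio undefined for identical noise inputs")
    dw = float(np.linalg.norm(np.asarray(w1) - np.asarray(w2)))
    return -min(tau, dw / dz)


def _diversity_term(fake: Tensor, z: np.ndarray, tau: float) -> Tensor:
    """Differentiable batch version: pair consecutive generator draws."""
    B = fake.shape[0]
    half = B // 2
    if half == 0:
        return Tensor(0.0)
    w1 = fake[0 : 2 * half : 2].reshape(half, -1)
    w2 = fake[1 : 2 * half : 2].reshape(half, -1)
    dz = z[0 : 2 * half : 2].reshape(half, -1) - z[1 : 2 * half : 2].reshape(half, -1)
    dz_norm = np.linalg.norm(dz, axis=1)
    if np.any(dz_norm == 0.0):
        raise GanError("diversity ratio undefined for identical noise inputs")
    diff = w1 - w2
    dw = ((diff * diff).sum(axis=1) + 1e-12).pow(0.5)
    ratio = dw * Tensor(1.0 / dz_norm)
    capped = tau - relu(Tensor(np.full(half, tau)) - ratio)  # min(tau, ratio)
    return -capped.mean()


class ConditionalGan(BaseEstimator):
    """Label-conditioned recurrent GAN for 60 × 6 windows.

    scikit-learn style estimator: ``fit(X, y)`` trains on windows
    ``X`` of shape (N, 60, 6) with binary labels ``y``; ``sample``
    draws label-conditioned synthetic windows.  ``privacy`` accepts a
    :class:`wearsynth.dp.PrivacySpec` to train the discriminator with
    DP-Adam (DP-CGAN).

    Defaults follow the tuned non-private setting: λ = 8, learning rate
    2e-4, batch 64, 1600 epochs; the private setting switches to the
    privacy spec's learning rate (1e-3) per its own schedule.
    """

    def __init__(self, lambda_div: float = 8.0, tau: float = 1.0,
                 learning_rate: float = 2e-4, batch_size: int = 64,
                 epochs: int = 1600, noise_dim: int = 50,
                 gen_widths: tuple[int, int] = (128, 128),
                 disc_widths: tuple[int, int] = (128, 64),
                 recurrent_noise: bool = True,
                 privacy: dp_mod.PrivacySpec | None = None,
                 random_state: int | None = None):
        self.lambda_div = lambda_div
        self.tau = tau
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.noise_dim = noise_dim
        self.gen_widths = gen_widths
        self.disc_widths = disc_widths
        self.recurrent_noise = recurrent_noise
        self.privacy = privacy
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _draw_noise(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.recurrent_noise:
            return rng.standard_normal((n, WINDOW_S, self.noise_dim))
        z = rng.standard_normal((n, 1, self.noise_dim))
        return np.repeat(z, WINDOW_S, axis=1)

    def _validate(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or X.shape[1:] != (WINDOW_S, N_SIGNALS):
            raise GanError(
                f"X must have shape (N, {WINDOW_S}, {N_SIGNALS}), got {X.shape}"
            )
        if len(X) == 0:
            raise GanError("X is empty")
        if len(y) != len(X):
            raise GanError("X and y length mismatch")
        if set(np.unique(y)) != {0, 1}:
            raise GanError("training needs both stress and non-stress windows")
        return X, y

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        if isinstance(X, WindowSet):
            X, y = X.windows, X.labels
        if y is None:
            raise GanError("y (window labels) is required")
        X, y = self._validate(X, np.asarray(y))
        if self.lambda_div < 0:
            raise GanError(f"lambda_div must be >= 0, got {self.lambda_div}")
        if self.epochs < 0 or self.batch_size < 1:
            raise GanError("epochs must be >= 0 and batch_size >= 1")
        rng = np.random.default_rng(self.random_state)
        self.generator_ = _Generator(self.noise_dim, tuple(self.gen_widths), rng)
        self.discriminator_ = _Discriminator(tuple(self.disc_widths), rng)
        self.loss_trace_ = []
        self.noise_multiplier_ = 0.0
        self.accountant_ = None

        private = self.privacy is not None and self.privacy.is_private
        if private:
            spec = self.privacy
            unique_n = spec.unique_n if spec.unique_n is not None else len(X)
            eff_epochs = (spec.effective_epochs if spec.effective_epochs is not None
                          else max(1, self.epochs))
            calib = dp_mod.PrivacySpec(
                epsilon=spec.epsilon, delta=spec.delta, clip_norm=spec.clip_norm,
                batch_size=spec.batch_size, unique_n=unique_n,
                effective_epochs=eff_epochs, learning_rate=spec.learning_rate,
            )
            self.noise_multiplier_ = (spec.noise_multiplier
                                      if spec.noise_multiplier is not None
                                      else dp_mod.calibrate_noise(calib))
            q = calib.sampling_rate
            self.accountant_ = dp_mod.AccountantState(
                sigma=self.noise_multiplier_, q=q, delta=spec.delta
            )
            batch_size = spec.batch_size
            d_lr = spec.learning_rate
        else:
            batch_size = self.batch_size
            d_lr = self.learning_rate

        opt_g = Adam(self.generator_.parameters(), lr=self.learning_rate)
        opt_d = Adam(self.discriminator_.parameters(), lr=d_lr)
        n = len(X)

        for _epoch in range(self.epochs):
            d_losses, g_losses = [], []
            if private:
                # Poisson sampling at rate q, as assumed by the accountant
                steps = max(1, n // batch_size)
                batches = []
                for _ in range(steps):
                    take = np.flatnonzero(rng.random(n) < self.accountant_.q)
                    if take.size:
                        batches.append(take)
            else:
                order = rng.permutation(n)
                steps = max(1, n // batch_size)
                batches = [order[i * batch_size : (i + 1) * batch_size]
                           for i in range(steps)]
                batches = [b for b in batches if b.size]
            for idx in batches:
                xb, yb = X[idx], y[idx]
                onehot = _one_hot(yb)
                # --- discriminator step
                z = self._draw_noise(len(idx), rng)
                fake = self.generator_(Tensor(z), onehot).detach()
                if private:
                    d_loss_val = self._dp_discriminator_step(
                        opt_d, xb, fake.data, onehot, rng)
                    self.accountant_.step()
                else:
                    self.discriminator_.zero_grad()
                    d_real = self.discriminator_(Tensor(xb), onehot)
                    d_fake = self.discriminator_(fake, onehot)
                    d_loss = (binary_cross_entropy(d_real, np.ones(len(idx)))
                              + binary_cross_entropy(d_fake, np.zeros(len(idx))))
                    d_loss.backward()
                    opt_d.step()
                    d_loss_val = float(d_loss.data)
                # --- generator step (never privatized)
                self.generator_.zero_grad()
                z = self._draw_noise(len(idx), rng)
                fake = self.generator_(Tensor(z), onehot)
                g_adv = binary_cross_entropy(
                    self.discriminator_(fake, onehot), np.ones(len(idx)))
                g_loss = g_adv + self.lambda_div * _diversity_term(fake, z, self.tau)
                g_loss.backward()
                opt_g.step()
                g_loss_val = float(g_loss.data)
                if not (math.isfinite(d_loss_val) and math.isfinite(g_loss_val)):
                    raise RuntimeError(
                        f"non-finite GAN loss at epoch {_epoch}: "
                        f"D={d_loss_val}, G={g_loss_val}"
                    )
                d_losses.append(d_loss_val)
                g_losses.append(g_loss_val)
            self.loss_trace_.append(
                {"epoch": _epoch,
                 "d_loss": float(np.mean(d_losses)) if d_losses else math.nan,
                 "g_loss": float(np.mean(g_losses)) if g_losses else math.nan}
            )
        self.n_features_in_ = WINDOW_S * N_SIGNALS
        return self

    def _dp_discriminator_step(self, opt_d: Adam, xb: np.ndarray,
                               fake: np.ndarray, onehot: np.ndarray,
                               rng: np.random.Generator) -> float:
        """One DP-Adam discriminator update: per-microbatch (single
        real + single fake example) gradients, clipped to C and noised."""
        spec = self.privacy
        params = self.discriminator_.parameters()
        per_example = []
        losses = []
        for i in range(len(xb)):
            self.discriminator_.zero_grad()
            oh = onehot[i : i + 1]
            d_real = self.discriminator_(Tensor(xb[i : i + 1]), oh)
            d_fake = self.discriminator_(Tensor(fake[i : i + 1]), oh)
            loss = (binary_cross_entropy(d_real, np.ones(1))
                    + binary_cross_entropy(d_fake, np.zeros(1)))
            loss.backward()
            grads = [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
                     for p in params]
            per_example.append(clip_global_norm(grads, spec.clip_norm))
            losses.append(float(loss.data))
        noisy = []
        for j in range(len(params)):
            total = np.sum([g[j] for g in per_example], axis=0)
            noise = rng.normal(
                0.0, self.noise_multiplier_ * spec.clip_norm, size=total.shape)
            noisy.append((total + noise) / spec.batch_size)
        opt_d.step(grads=noisy)
        return float(np.mean(losses))

    def sample(self, n: int, labels: np.ndarray | None = None,
               random_state: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` windows; labels default to fair coin flips.

        Returns ``(windows, labels)`` with windows in [0, 1] by
        construction (sigmoid output head).
        """
        if not hasattr(self, "generator_"):
            raise GanError("sample() requires a fitted (or epochs=0) estimator")
        if n < 1:
            raise GanError(f"n must be >= 1, got {n}")
        rng = np.random.default_rng(random_state)
        if labels is None:
            labels = rng.integers(0, 2, size=n)
        labels = np.asarray(labels, dtype=int)
        if len(labels) != n:
            raise GanError("labels length must equal n")
        z = self._draw_noise(n, rng)
        out = self.generator_(Tensor(z), _one_hot(labels))
        return out.data.copy(), labels

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if not hasattr(self, "generator_"):
            raise GanError("nothing to save: estimator not fitted")
        cfg = self.get_params()
        cfg["privacy"] = None if self.privacy is None else {
            k: (None if v is None else (v if np.isfinite(v) or not isinstance(v, float) else "inf"))
            for k, v in vars(self.privacy).items() if not k.startswith("_")
        }
        arrays = {f"g{i}": a for i, a in enumerate(self.generator_.state_arrays())}
        arrays.update({f"d{i}": a for i, a in enumerate(self.discriminator_.state_arrays())})
        np.savez(path, config=json.dumps(cfg, default=str),
                 noise_multiplier=self.noise_multiplier_, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ConditionalGan":
        z = np.load(path, allow_pickle=False)
        cfg = json.loads(str(z["config"]))
        cfg.pop("privacy", None)
        for key in ("gen_widths", "disc_widths"):
            if isinstance(cfg.get(key), str):
                cfg[key] = tuple(json.loads(cfg[key].replace("(", "[").replace(")", "]")))
            elif isinstance(cfg.get(key), list):
                cfg[key] = tuple(cfg[key])
        est = cls(**cfg)
        rng = np.random.default_rng(0)
        est.generator_ = _Generator(est.noise_dim, tuple(est.gen_widths), rng)
        est.discriminator_ = _Discriminator(tuple(est.disc_widths), rng)
        g_keys = sorted((k for k in z.files if k.startswith("g") and k != "config"),
                        key=lambda s: int(s[1:]))
        d_keys = sorted((k for k in z.files if k.startswith("d")),
                        key=lambda s: int(s[1:]))
        est.generator_.load_state_arrays([z[k] for k in g_keys])
        est.discriminator_.load_state_arrays([z[k] for k in d_keys])
        est.noise_multiplier_ = float(z["noise_multiplier"])
        est.loss_trace_ = []
        return est


@dataclass
class SyntheticCohort:
    """Generated subjects, each about one real subject's worth of windows."""

    subjects: list[WindowSet]

    def all_windows(self) -> WindowSet:
        return WindowSet.concat(self.subjects)

    @property
    def stress_share(self) -> float:
        all_ = self.all_windows()
        return float(all_.labels.mean())


def synthesize_subjects(gan: ConditionalGan, n_subjects: int,
                        stress_share: float = 0.30, subject_minutes: int = 36,
                        random_state: int | None = None) -> SyntheticCohort:
    """Sample subject-sized labeled cohorts from a (possibly untrained) GAN.

    Each synthetic subject gets one 60-s window per minute; the stress
    count per subject is fixed to round(stress_share × windows), giving
    11 of 36 at the default 30% target — matching the real cohort's
    class balance.
    """
    if n_subjects < 1:
        raise GanError(f"n_subjects must be >= 1, got {n_subjects}")
    if not 0.0 <= stress_share <= 1.0:
        raise GanError(f"stress_share must be in [0, 1], got {stress_share}")
    rng = np.random.default_rng(random_state)
    n_win = max(1, int(math.ceil(subject_minutes * 60 / WINDOW_S)))
    n_stress = int(round(stress_share * n_win))
    subjects = []
    for i in range(n_subjects):
        labels = np.array([1] * n_stress + [0] * (n_win - n_stress))
        rng.shuffle(labels)
        windows, labels = gan.sample(
            n_win, labels=labels,
            random_state=int(rng.integers(0, 2**31 - 1)))
        subjects.append(
            WindowSet(
                windows=windows,
                labels=labels,
                subjects=np.array([f"SYN{i + 1:03d}"] * n_win, dtype=object),
                stride_s=WINDOW_S,
            )
        )
    return SyntheticCohort(subjects=subjects)


def train_cgan(windows: WindowSet, **params) -> ConditionalGan:
    """Functional wrapper: fit a :class:`ConditionalGan` on a WindowSet."""
    est = ConditionalGan(**params)
    return est.fit(windows.windows, windows.labels)
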