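"""Differential-privacy machinery for private training.

Implements the (ε, δ) accounting stack used by the private conditional
GAN and the private classifiers: per-example gradient clipping, a
Rényi-DP accountant for the Poisson-subsampled Gaussian mechanism,
noise calibration by binary search, the δ-selection rule
(largest power of ten strictly below 1/n), and the unique-window
accounting rule for overlapping sliding windows (account with the
unique window count but double the epochs, since a 30-s slide re-samples
every unique point twice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .nn.optim import clip_global_norm

__all__ = [
    "PrivacySpec",
    "AccountantState",
    "DPError",
    "clip_per_example",
    "sliding_window_accounting",
    "select_delta",
    "epsilon_spent",
    "calibrate_noise",
]

SIGMA_BRACKET = (0.3, 100.0)
#: Rényi orders used by the subsampled accountant (integers; the
#: binomial-expansion bound is valid at integer orders)
DEFAULT_ORDERS = tuple(range(2, 257))


class DPError(ValueError):
    pass


@dataclass
class PrivacySpec:
    """Privacy target and the training geometry the accountant needs.

    ``epsilon=math.inf`` means non-private training.  ``delta`` defaults
    to 1e-3, matching the δ ≪ 1/n rule at n ≈ 496 unique windows.
    ``effective_epochs`` is the accounting epoch count — actual epochs
    times the sliding multiplier from
    :func:`sliding_window_accounting`.
    """

    epsilon: float = math.inf
    delta: float = 1e-3
    clip_norm: float = 1.0
    batch_size: int = 8
    microbatches: int | None = None
    unique_n: int | None = None
    effective_epochs: int | None = None
    noise_multiplier: float | None = None
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.epsilon > 0):
            raise DPError(f"epsilon must be positive (or inf), got {self.epsilon}")
        if not 0 < self.delta < 1:
            raise DPError(f"delta must be in (0, 1), got {self.delta}")
        if self.clip_norm <= 0:
            raise DPError(f"clip_norm must be positive, got {self.clip_norm}")
        if self.batch_size < 1:
            raise DPError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.microbatches is None:
            self.microbatches = self.batch_size
        if self.unique_n is not None and self.delta >= 1.0 / self.unique_n:
            raise DPError(
                f"delta {self.delta} violates delta < 1/unique_n "
                f"= {1.0 / self.unique_n:.2e}"
            )

    @property
    def is_private(self) -> bool:
        return math.isfinite(self.epsilon)

    @property
    def sampling_rate(self) -> float:
        if self.unique_n is None:
            raise DPError("unique_n not set")
        return min(1.0, self.batch_size / self.unique_n)

    @property
    def steps(self) -> int:
        if self.unique_n is None or self.effective_epochs is None:
            raise DPError("unique_n and effective_epochs must be set")
        return max(1, int(round(self.effective_epochs * self.unique_n
                                / self.batch_size)))


def clip_per_example(grads, clip_norm: float):
    """Clip each example's gradient(s) to global L2 norm <= ``clip_norm``.

    ``grads`` is either an (n, d) array of flat per-example gradients or
    a list of per-example lists of arrays (one array per parameter).
    """
    if clip_norm <= 0:
        raise DPError(f"clip_norm must be positive, got {clip_norm}")
    if isinstance(grads, np.ndarray):
        norms = np.linalg.norm(grads.reshape(len(grads), -1), axis=1)
        scale = np.minimum(1.0, clip_norm / np.maximum(norms, 1e-300))
        return grads * scale.reshape((-1,) + (1,) * (grads.ndim - 1))
    return [clip_global_norm(g, clip_norm) for g in grads]


def sliding_window_accounting(n_windows_sliding: int,
                              n_windows_unique: int) -> tuple[int, int]:
    """Accounting rule for overlapping sliding windows.

    A 30-s slide over 60-s windows roughly doubles the window count
    without adding new unique seconds, so noise is calibrated with the
    unique count while the accounted epochs are doubled to cover the
    doubled per-point sampling probability.  With no sliding the
    multiplier is 1.
    """
    if n_windows_unique < 1 or n_windows_sliding < 1:
        raise DPError("window counts must be >= 1")
    if n_windows_sliding < n_windows_unique:
        raise DPError(
            f"sliding count {n_windows_sliding} < unique count {n_windows_unique}"
        )
    multiplier = 2 if n_windows_sliding > n_windows_unique else 1
    return n_windows_unique, multiplier


def select_delta(unique_n: int) -> float:
    """Largest power of ten strictly below 1/unique_n (the δ ≪ 1/n rule)."""
    if unique_n < 2:
        raise DPError(f"unique_n must be >= 2, got {unique_n}")
    k = 0
    while 10**k <= unique_n:
        k += 1
    return 10.0 ** (-k)


def _rdp_subsampled_gaussian(q: float, sigma: float, orders) -> np.ndarray:
    """Per-step RDP of the Poisson-subsampled Gaussian mechanism at
    integer orders (binomial-expansion upper bound)."""
    rdp = np.empty(len(orders))
    for j, alpha in enumerate(orders):
        a = int(alpha)
        ks = np.arange(a + 1)
        log_terms = (
            gammaln(a + 1) - gammaln(ks + 1) - gammaln(a - ks + 1)
            + (a - ks) * np.log1p(-q)
            + ks * np.log(q)
            + ks * (ks - 1) / (2.0 * sigma**2)
        )
        rdp[j] = logsumexp(log_terms) / (a - 1)
    return rdp


def _rdp_to_eps(rdp_total: np.ndarray, orders: np.ndarray, delta: float) -> float:
    """Convert composed RDP to (ε, δ) with the improved conversion
    ε = RDP(α) + log1p(-1/α) - (log δ + log α)/(α - 1), minimized over α."""
    orders = np.asarray(orders, dtype=float)
    eps = (
        rdp_total
        + np.log1p(-1.0 / orders)
        - (np.log(delta) + np.log(orders)) / (orders - 1.0)
    )
    return float(max(0.0, np.min(eps)))


def _analytic_gaussian_eps(sigma: float, delta: float) -> float:
    """Exact ε of the Gaussian mechanism (unit sensitivity) at δ,
    from the Gaussian-CDF characterization of its privacy curve."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    def delta_of(eps: float) -> float:
        return float(
            norm.cdf(0.5 / sigma - eps * sigma)
            - math.exp(eps) * norm.cdf(-0.5 / sigma - eps * sigma)
        )

    if delta_of(0.0) <= delta:
        return 0.0
    hi = 1.0
    while delta_of(hi) > delta and hi < 1e6:
        hi *= 2.0
    return float(brentq(lambda e: delta_of(e) - delta, 0.0, hi, xtol=1e-12))


def epsilon_spent(sigma: float, q: float, steps: int, delta: float,
                  orders=DEFAULT_ORDERS) -> float:
    """ε spent by ``steps`` subsampled-Gaussian steps at noise ``sigma``."""
    if sigma <= 0:
        return math.inf
    if not 0 < q <= 1:
        raise DPError(f"sampling rate must be in (0, 1], got {q}")
    if steps < 1:
        raise DPError(f"steps must be >= 1, got {steps}")
    if q == 1.0:
        # no subsampling: the composition of `steps` Gaussian mechanisms
        # is itself a Gaussian mechanism at sigma / sqrt(steps), for
        # which the exact analytic (ε, δ) curve is available
        return _analytic_gaussian_eps(sigma / math.sqrt(steps), delta)
    per_step = _rdp_subsampled_gaussian(q, sigma, orders)
    return _rdp_to_eps(steps * per_step, np.asarray(orders, dtype=float), delta)


def calibrate_noise(spec: PrivacySpec, tol: float = 1e-3,
                    max_iter: int = 60) -> float:
    """Smallest noise multiplier meeting the spec's ε target.

    Binary search over σ ∈ [0.3, 100]; non-private specs return 0.
    """
    if not spec.is_private:
        return 0.0
    q, steps = spec.sampling_rate, spec.steps
    lo, hi = SIGMA_BRACKET
    if epsilon_spent(hi, q, steps, spec.delta) > spec.epsilon:
        raise DPError(
            f"epsilon target {spec.epsilon} unreachable with sigma <= {hi}"
        )
    if epsilon_spent(lo, q, steps, spec.delta) <= spec.epsilon:
        return lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if epsilon_spent(mid, q, steps, spec.delta) <= spec.epsilon:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * hi:
            break
    return hi


@dataclass
class AccountantState:
    """Running privacy-loss tracker for a fixed (σ, q, δ) mechanism."""

    sigma: float
    q: float
    delta: float
    steps: int = 0
    _history: list[int] = field(default_factory=list, repr=False)

    def step(self, n: int = 1) -> None:
        if n < 1:
            raise DPError("step count must be >= 1")
        self.steps += n
        self._history.append(n)

    @property
    def epsilon(self) -> float:
        if self.steps == 0:
            return 0.0
        return epsilon_spent(self.sigma, self.q, self.steps, self.delta)
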