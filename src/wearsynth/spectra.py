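"""FFT spectral featurization of 60-s windows for the stress classifiers.

Each signal is cut into signal-specific subwindows (length chosen so
that upper frequency bound × subwindow length = 210), the magnitude
spectrum of every subwindow is placed on a fixed 210-bin grid (bins
above the data's Nyquist are exact zeros), and the spectra are averaged
over all subwindows of the 60-s window, giving one 6 × 210 feature
matrix per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures import SIGNALS
from .prep import WindowSet

N_POINTS = 210

#: (upper frequency bound in Hz, subwindow length in s) per signal family
DEFAULT_BANDS: dict[str, tuple[float, int]] = {
    "acc_x": (30.0, 7),
    "acc_y": (30.0, 7),
    "acc_z": (30.0, 7),
    "bvp": (7.0, 30),
    "eda": (7.0, 30),
    "temp": (6.0, 35),
}


class SpectraError(ValueError):
    pass


@dataclass(frozen=True)
class SpectraConfig:
    bands: dict[str, tuple[float, int]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    stride_s: float = 0.25
    n_points: int = N_POINTS

    def __post_init__(self) -> None:
        for name in SIGNALS:
            if name not in self.bands:
                raise SpectraError(f"bands missing signal {name!r}")
            upper, sub = self.bands[name]
            if round(upper * sub) != self.n_points:
                raise SpectraError(
                    f"{name!r}: upper_hz * subwindow_s = {upper * sub} "
                    f"!= {self.n_points}"
                )
        if self.stride_s <= 0:
            raise SpectraError(f"stride_s must be positive, got {self.stride_s}")


@dataclass
class SpectrumSet:
    """Per-window 6 × 210 averaged magnitude spectra."""

    features: np.ndarray  # (N, 6, 210), non-negative
    labels: np.ndarray    # (N,)
    subjects: np.ndarray  # (N,)

    def __len__(self) -> int:
        return int(self.features.shape[0])


def fft_subwindow_spectrum(samples: np.ndarray, fs: float, upper_hz: float,
                           n_points: int = N_POINTS) -> np.ndarray:
    """Magnitude spectrum of one subwindow on the fixed output grid.

    Output bin k corresponds to frequency k * upper_hz / n_points
    (equivalently k / subwindow_s).  Bins beyond the data's Nyquist
    frequency cannot be estimated from the samples and are zero-padded,
    the DC bin is retained.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise SpectraError("empty subwindow")
    mag = np.abs(np.fft.rfft(samples))
    out = np.zeros(n_points)
    k = min(mag.size, n_points)
    out[:k] = mag[:k]
    return out


def featurize_window(window: np.ndarray, cfg: SpectraConfig | None = None,
                     fs: float = 1.0) -> np.ndarray:
    """Average subwindow spectra of one 60 × 6 window → 6 × 210 features.

    The configured 0.25-s subwindow stride is finer than the 1 Hz data
    grid, so the effective stride is max(1, round(stride * fs)) samples.
    """
    cfg = cfg or SpectraConfig()
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != len(SIGNALS):
        raise SpectraError(f"expected a (T, {len(SIGNALS)}) window, got {window.shape}")
    T = window.shape[0]
    stride = max(1, int(round(cfg.stride_s * fs)))
    out = np.empty((len(SIGNALS), cfg.n_points))
    for i, name in enumerate(SIGNALS):
        upper, sub_s = cfg.bands[name]
        sub_n = int(round(sub_s * fs))
        if sub_n > T:
            raise SpectraError(
                f"{name!r}: subwindow {sub_n} samples exceeds window length {T}"
            )
        starts = range(0, T - sub_n + 1, stride)
        spectra = [
            fft_subwindow_spectrum(window[s : s + sub_n, i], fs, upper, cfg.n_points)
            for s in starts
        ]
        out[i] = np.mean(spectra, axis=0)
    return out


def featurize_windows(windows: WindowSet, cfg: SpectraConfig | None = None) -> SpectrumSet:
    cfg = cfg or SpectraConfig()
    feats = np.stack([featurize_window(w, cfg) for w in windows.windows])
    return SpectrumSet(features=feats, labels=windows.labels.copy(),
                       subjects=windows.subjects.copy())


def spectral_power(features: np.ndarray) -> np.ndarray:
    """Mean squared-magnitude spectral power per signal.

    ``features`` is (N, 6, 210) magnitude spectra; returns (N, 6).
    This is the summary statistic behind the logistic-regression
    baseline and the stress/non-stress percentage-change comparison.
    """
    features = np.asarray(features, dtype=float)
    return np.mean(features**2, axis=-1)


class SpectralFeaturizer:
    """scikit-learn style transformer: (N, 60, 6) windows → spectra.

    ``output`` selects the shape: ``"matrix"`` keeps (N, 6, 210) for the
    neural classifiers, ``"power"`` gives the (N, 6) mean spectral power
    used by the linear baseline.
    """

    def __init__(self, cfg: SpectraConfig | None = None, output: str = "matrix"):
        self.cfg = cfg
        self.output = output

    def get_params(self, deep: bool = True):
        return {"cfg": self.cfg, "output": self.output}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        if self.output not in ("matrix", "power"):
            raise SpectraError(f"unknown output mode {self.output!r}")
        self.cfg_ = self.cfg or SpectraConfig()
        return self

    def transform(self, X):
        if not hasattr(self, "cfg_"):
            self.fit(X)
        X = X.windows if isinstance(X, WindowSet) else np.asarray(X, dtype=float)
        feats = np.stack([featurize_window(w, self.cfg_) for w in X])
        if self.output == "power":
            return spectral_power(feats)
        return feats

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
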