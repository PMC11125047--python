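"""Synthetic-data quality suite.

Four complementary views of how close a synthetic window set is to a
real one: 2-D embeddings (PCA fitted on the real data, t-SNE fitted
jointly), Pearson correlation matrices between the six signals and the
stress label with two-sided p-values, per-stratum value densities, and
a classifier two-sample test (C2ST) with a Gaussian Naive Bayes
discriminator — held-out accuracy near 0.5 means the sets are
indistinguishable.  Also provides the symmetric average-percentage-
change statistic used for stress vs non-stress spectral-power
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.naive_bayes import GaussianNB

from .fixtures import SIGNALS
from .prep import WindowSet

__all__ = [
    "CorrelationReport",
    "C2STResult",
    "QualityError",
    "correlation_with_p",
    "c2st",
    "embed_2d",
    "density_compare",
    "avg_pct_change",
]

COLUMNS = SIGNALS + ("label",)


class QualityError(ValueError):
    pass


@dataclass
class CorrelationReport:
    """7 × 7 Pearson r and two-sided p over the six signals + label."""

    r: np.ndarray
    p: np.ndarray
    columns: tuple[str, ...] = COLUMNS
    degenerate: list[str] = field(default_factory=list)


@dataclass
class C2STResult:
    accuracy: float
    accuracy_stress: float | None
    accuracy_nonstress: float | None
    n_train: int
    n_test: int
    seed: int


def _design_matrix(windows: WindowSet, per: str) -> np.ndarray:
    """(M, 7) value matrix: six signal columns + the label column."""
    if per == "second":
        vals = windows.windows.reshape(-1, len(SIGNALS))
        labs = np.repeat(windows.labels, windows.windows.shape[1])
    elif per == "window":
        vals = windows.windows.mean(axis=1)
        labs = windows.labels
    else:
        raise QualityError(f"per must be 'second' or 'window', got {per!r}")
    return np.column_stack([vals, labs.astype(float)])


def correlation_with_p(windows: WindowSet, per: str = "second") -> CorrelationReport:
    """Pairwise Pearson correlation (with p-values) of signals and label.

    Computed on pooled per-second values by default, with the window
    label repeated for each of its seconds; ``per="window"`` uses
    window means instead.  A zero-variance column is flagged and
    reported as r = 0, p = 1.
    """
    if len(windows) < 3:
        raise QualityError("need at least 3 windows for correlations")
    mat = _design_matrix(windows, per)
    k = mat.shape[1]
    r = np.eye(k)
    p = np.zeros((k, k))
    degenerate = [COLUMNS[i] for i in range(k) if np.std(mat[:, i]) == 0.0]
    for i in range(k):
        for j in range(i + 1, k):
            if COLUMNS[i] in degenerate or COLUMNS[j] in degenerate:
                rij, pij = 0.0, 1.0
            else:
                rij, pij = sstats.pearsonr(mat[:, i], mat[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return CorrelationReport(r=r, p=p, degenerate=degenerate)


def _flat(windows: WindowSet) -> np.ndarray:
    return windows.windows.reshape(len(windows), -1)


def c2st(real: WindowSet, synth: WindowSet, split: float = 0.5,
         seed: int = 0) -> C2STResult:
    """Classifier two-sample test with a Gaussian Naive Bayes model.

    Pools are equalized by downsampling the larger side, split
    ``split``/(1-split) into train/test within each side, and the
    flattened windows are classified real-vs-synthetic; the held-out
    accuracy is reported overall and per stress stratum.
    """
    if len(real) < 4 or len(synth) < 4:
        raise QualityError("c2st needs at least 4 windows per side")
    rng = np.random.default_rng(seed)
    n = min(len(real), len(synth))
    idx_r = rng.choice(len(real), size=n, replace=False)
    idx_s = rng.choice(len(synth), size=n, replace=False)
    n_train = max(1, int(round(split * n)))

    def side(ws: WindowSet, idx: np.ndarray):
        X = _flat(ws)[idx]
        strata = ws.labels[idx]
        return X[:n_train], X[n_train:], strata[n_train:]

    Xr_tr, Xr_te, str_r = side(real, idx_r)
    Xs_tr, Xs_te, str_s = side(synth, idx_s)
    clf = GaussianNB()
    X_tr = np.vstack([Xr_tr, Xs_tr])
    y_tr = np.concatenate([np.ones(len(Xr_tr)), np.zeros(len(Xs_tr))])
    clf.fit(X_tr, y_tr)
    X_te = np.vstack([Xr_te, Xs_te])
    y_te = np.concatenate([np.ones(len(Xr_te)), np.zeros(len(Xs_te))])
    pred = clf.predict(X_te)
    correct = pred == y_te
    strata = np.concatenate([str_r, str_s])

    def stratum_acc(lab: int) -> float | None:
        mask = strata == lab
        return float(correct[mask].mean()) if mask.any() else None

    return C2STResult(
        accuracy=float(correct.mean()),
        accuracy_stress=stratum_acc(1),
        accuracy_nonstress=stratum_acc(0),
        n_train=len(X_tr),
        n_test=len(X_te),
        seed=seed,
    )


def embed_2d(real: WindowSet, synth: WindowSet, method: str = "pca",
             seed: int = 0):
    """Project both window sets into 2-D.

    PCA is fitted on the real windows only (the synthetic set is mapped
    into the real data's component space) and per-signal loading
    magnitudes of the two components are returned; t-SNE is fitted
    jointly on the pooled windows.
    Returns ``(coords_real, coords_synth, loadings | None)`` where
    loadings has shape (2, 6).
    """
    if len(real) < 3 or len(synth) < 3:
        raise QualityError("need at least 3 windows per side to embed")
    Xr, Xs = _flat(real), _flat(synth)
    if method == "pca":
        pca = PCA(n_components=2, random_state=seed)
        coords_r = pca.fit_transform(Xr)
        coords_s = pca.transform(Xs)
        comp = pca.components_.reshape(2, real.windows.shape[1], len(SIGNALS))
        loadings = np.sqrt((comp**2).sum(axis=1))  # (2, 6) per-signal magnitude
        return coords_r, coords_s, loadings
    if method == "tsne":
        pooled = np.vstack([Xr, Xs])
        perplexity = min(30.0, (len(pooled) - 1) / 3.0)
        ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                  init="pca")
        coords = ts.fit_transform(pooled)
        return coords[: len(Xr)], coords[len(Xr):], None
    raise QualityError(f"unknown embedding method {method!r}")


def density_compare(real: WindowSet, synth: WindowSet, signal: str,
                    bins: int = 50) -> dict:
    """Per-stratum normalized value densities of one signal over [0, 1].

    Returns {"edges": ..., "real": {label: density}, "synth": ...,
    "missing": [...]} where each density integrates to 1; empty strata
    are omitted and flagged in ``missing``.
    """
    if signal not in SIGNALS:
        raise QualityError(f"unknown signal {signal!r}")
    ch = SIGNALS.index(signal)
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = {"edges": edges, "real": {}, "synth": {}, "missing": []}
    for key, ws in (("real", real), ("synth", synth)):
        for lab in (0, 1):
            vals = ws.windows[ws.labels == lab][:, :, ch].ravel()
            if vals.size == 0:
                out["missing"].append(f"{key}/{lab}")
                continue
            density, _ = np.histogram(vals, bins=edges, density=True)
            out[key][lab] = density
    return out


def avg_pct_change(a: float, b: float) -> float:
    """Symmetric percentage change of two means, relative to their average:
    100 · |a − b| / ((a + b) / 2)."""
    if a + b == 0:
        raise QualityError("avg_pct_change undefined when a + b == 0")
    return float(100.0 * abs(a - b) / ((a + b) / 2.0))
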