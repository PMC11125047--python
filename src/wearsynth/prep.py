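"""Raw multi-rate sessions → aligned, binary-labeled, normalized 60-s windows.

Four steps: Fourier downsampling of every channel to a common 1 Hz grid,
relabeling neutral/amusement into a single non-stress class, global
min–max normalization to [0, 1], and 60-s windowing with an optional
30-s slide and majority-vote window labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import resample as fourier_resample

from .fixtures import SIGNALS, RawSession


class PrepError(ValueError):
    pass


@dataclass
class AlignedSession:
    """Six channels on a shared 1 Hz time base with binary labels."""

    subject_id: str
    data: np.ndarray    # (T, 6), channel order wearsynth.fixtures.SIGNALS
    labels: np.ndarray  # (T,), 0 = non-stress, 1 = stress

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.labels.shape[0]:
            raise PrepError(
                f"data length {self.data.shape[0]} != label length "
                f"{self.labels.shape[0]}"
            )
        if self.data.shape[1] != len(SIGNALS):
            raise PrepError(f"expected {len(SIGNALS)} channels, got {self.data.shape[1]}")


@dataclass
class NormStats:
    """Per-signal min/max used for [0, 1] scaling."""

    mins: np.ndarray  # (6,)
    maxs: np.ndarray  # (6,)

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise PrepError("NormStats requires max >= min per signal")


@dataclass
class WindowSet:
    """Labeled 60 × 6 windows — the common currency of the pipeline."""

    windows: np.ndarray            # (N, 60, 6) in [0, 1]
    labels: np.ndarray             # (N,) binary
    subjects: np.ndarray           # (N,) str
    stride_s: int = 60
    starts: np.ndarray | None = None  # (N,) window start second

    def __post_init__(self) -> None:
        n = self.windows.shape[0]
        if self.labels.shape[0] != n or self.subjects.shape[0] != n:
            raise PrepError("windows / labels / subjects length mismatch")

    def __len__(self) -> int:
        return int(self.windows.shape[0])

    @classmethod
    def concat(cls, parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise PrepError("cannot concatenate an empty list of WindowSets")
        return cls(
            windows=np.concatenate([p.windows for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            subjects=np.concatenate([p.subjects for p in parts]),
            stride_s=parts[0].stride_s,
        )

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            windows=self.windows[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            stride_s=self.stride_s,
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "windows.npz", windows=self.windows, labels=self.labels,
                 subjects=self.subjects.astype(str), stride_s=self.stride_s)
        starts = self.starts if self.starts is not None else np.full(len(self), -1)
        with open(out / "index.csv", "w") as fh:
            fh.write("subject,window_start_s,label\n")
            for sid, st, lab in zip(self.subjects, starts, self.labels):
                fh.write(f"{sid},{int(st)},{int(lab)}\n")

    @classmethod
    def load(cls, in_dir: str | Path) -> "WindowSet":
        z = np.load(Path(in_dir) / "windows.npz", allow_pickle=False)
        return cls(windows=z["windows"], labels=z["labels"],
                   subjects=z["subjects"].astype(str), stride_s=int(z["stride_s"]))


def merge_labels(labels3: np.ndarray) -> np.ndarray:
    """Fold the 3-state track into binary: stress (1) vs non-stress (0).

    Neutral (0) and amusement (2) both become non-stress; anything else
    is rejected with the offending positions listed.
    """
    labels3 = np.asarray(labels3)
    bad = np.flatnonzero(~np.isin(labels3, (0, 1, 2)))
    if bad.size:
        raise PrepError(
            f"unknown label codes at positions {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else "")
        )
    return (labels3 == 1).astype(np.int64)


def resample_to_1hz(session: RawSession) -> AlignedSession:
    """Fourier-downsample every channel to 1 Hz and merge the labels.

    Uses spectral resampling (truncate the spectrum to the new
    bandwidth, inverse transform), which preserves the DC component and
    low-frequency content of each channel.  A trailing partial second of
    samples is dropped.
    """
    T = session.duration_s
    if T < 1:
        raise PrepError("session has an empty label track")
    cols = []
    for name in SIGNALS:
        x = np.asarray(session.signals[name], dtype=float)
        if x.size == 0:
            raise PrepError(f"signal {name!r} is empty")
        rate = session.rates[name]
        if rate < 1.0:
            raise PrepError(f"signal {name!r} rate {rate} Hz is below 1 Hz")
        if int(len(x) / rate) != T:
            raise PrepError(
                f"signal {name!r}: {len(x)} samples at {rate} Hz span "
                f"{int(len(x) / rate)} s but the label track has {T} s"
            )
        x = x[: int(round(rate * T))]
        cols.append(fourier_resample(x, T))
    data = np.column_stack(cols)
    return AlignedSession(
        subject_id=session.subject_id,
        data=data,
        labels=merge_labels(session.labels),
    )


def minmax_normalize(
    sessions: list[AlignedSession], stats: NormStats | None = None
) -> tuple[list[AlignedSession], NormStats]:
    """Scale each signal to [0, 1] with global per-signal min/max.

    Without precomputed ``stats`` the extrema are taken over all given
    sessions jointly (e.g. the training fold); with ``stats`` they are
    applied as-is and the result is clipped to [0, 1], which is how a
    held-out subject is scaled with training statistics.  A constant
    signal maps to all zeros.
    """
    if not sessions:
        raise PrepError("minmax_normalize needs at least one session")
    if stats is None:
        stacked = np.concatenate([s.data for s in sessions], axis=0)
        stats = NormStats(mins=stacked.min(axis=0), maxs=stacked.max(axis=0))
    span = stats.maxs - stats.mins
    safe_span = np.where(span > 0, span, 1.0)
    out = []
    for s in sessions:
        scaled = (s.data - stats.mins) / safe_span
        scaled[:, span == 0] = 0.0
        np.clip(scaled, 0.0, 1.0, out=scaled)
        out.append(AlignedSession(s.subject_id, scaled, s.labels.copy()))
    return out, stats


def slice_windows(
    session: AlignedSession,
    window_s: int = 60,
    stride_s: int = 30,
    tie_label: int = 1,
) -> WindowSet:
    """Cut a session into 60-s windows every ``stride_s`` seconds.

    Windows are 0-based half-open second intervals; the trailing partial
    window is dropped, so the count is floor((T - window) / stride) + 1.
    A window's label is the majority of its per-second labels; an exact
    tie goes to ``tie_label`` (stress by default, favoring detector
    sensitivity).
    """
    T = session.data.shape[0]
    if T < window_s:
        raise PrepError(f"session length {T} s is shorter than the {window_s}-s window")
    if stride_s < 1:
        raise PrepError(f"stride_s must be >= 1, got {stride_s}")
    n = (T - window_s) // stride_s + 1
    starts = np.arange(n) * stride_s
    windows = np.stack([session.data[s : s + window_s] for s in starts])
    votes = np.array([session.labels[s : s + window_s].sum() for s in starts])
    labels = np.where(
        votes * 2 > window_s, 1, np.where(votes * 2 < window_s, 0, tie_label)
    ).astype(np.int64)
    return WindowSet(
        windows=windows,
        labels=labels,
        subjects=np.array([session.subject_id] * n, dtype=object),
        stride_s=stride_s,
        starts=starts,
    )


def prepare_cohort(
    sessions: list[RawSession],
    stride_s: int = 30,
    stats: NormStats | None = None,
    tie_label: int = 1,
) -> tuple[WindowSet, NormStats]:
    """Full preparation pipeline: resample → merge → normalize → window."""
    aligned = [resample_to_1hz(s) for s in sessions]
    normed, stats = minmax_normalize(aligned, stats)
    parts = [slice_windows(s, stride_s=stride_s, tie_label=tie_label) for s in normed]
    return WindowSet.concat(parts), stats
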