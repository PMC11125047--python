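"""Optional adapter for the native WESAD per-subject serialized bundles.

WESAD ships one pickle per subject containing wrist-device channels
(``signal.wrist``: ACC at 32 Hz, BVP at 64 Hz, EDA and TEMP at 4 Hz)
and a 700 Hz study-protocol label track.  This adapter converts such a
bundle into the package's :class:`~wearsynth.fixtures.RawSession`
currency: protocol labels are reduced per second (majority vote) and
mapped to the 3-state affect coding (neutral = 0, stress = 1,
amusement = 2); seconds outside these conditions are dropped.

The dataset itself is not distributed with the package; everything here
degrades to a clear error when the files are absent.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .fixtures import RawSession

#: WESAD protocol label codes
_PROTOCOL_BASELINE = 1
_PROTOCOL_STRESS = 2
_PROTOCOL_AMUSEMENT = 3

_WRIST_RATES = {"ACC": 32.0, "BVP": 64.0, "EDA": 4.0, "TEMP": 4.0}
_LABEL_RATE = 700


def map_protocol_labels(protocol: np.ndarray) -> np.ndarray:
    """Protocol codes → affect codes; unused conditions become -1.

    Baseline → neutral (0), stress → stress (1), amusement → amusement
    (2); transient/meditation/unused codes map to -1 (to be dropped).
    """
    protocol = np.asarray(protocol, dtype=int)
    out = np.full(protocol.shape, -1, dtype=np.int64)
    out[protocol == _PROTOCOL_BASELINE] = 0
    out[protocol == _PROTOCOL_STRESS] = 1
    out[protocol == _PROTOCOL_AMUSEMENT] = 2
    return out


def labels_per_second(label_track: np.ndarray, rate: int = _LABEL_RATE) -> np.ndarray:
    """Reduce a high-rate label track to one code per second by majority."""
    label_track = np.asarray(label_track, dtype=int)
    n_sec = len(label_track) // rate
    out = np.empty(n_sec, dtype=np.int64)
    for s in range(n_sec):
        chunk = label_track[s * rate : (s + 1) * rate]
        vals, counts = np.unique(chunk, return_counts=True)
        out[s] = vals[np.argmax(counts)]
    return out


def read_wesad_subject(path: str | Path) -> RawSession:
    """Load one WESAD subject pickle into a RawSession.

    Only seconds labeled neutral / stress / amusement are kept; every
    channel is cut to the matching contiguous sample ranges.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"WESAD bundle {path} not found; download the dataset separately")
    with open(path, "rb") as fh:
        bundle = pickle.load(fh, encoding="latin1")
    wrist = bundle["signal"]["wrist"]
    per_sec = labels_per_second(bundle["label"])
    affect = map_protocol_labels(per_sec)
    keep = affect >= 0
    keep_seconds = np.flatnonzero(keep)

    signals: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    acc = np.asarray(wrist["ACC"], dtype=float)
    for i, name in enumerate(("acc_x", "acc_y", "acc_z")):
        signals[name] = _take_seconds(acc[:, i], _WRIST_RATES["ACC"], keep_seconds)
        rates[name] = _WRIST_RATES["ACC"]
    for src, name in (("BVP", "bvp"), ("EDA", "eda"), ("TEMP", "temp")):
        arr = np.asarray(wrist[src], dtype=float).reshape(-1)
        signals[name] = _take_seconds(arr, _WRIST_RATES[src], keep_seconds)
        rates[name] = _WRIST_RATES[src]

    return RawSession(
        subject_id=path.stem,
        signals=signals,
        rates=rates,
        labels=affect[keep],
    )


def _take_seconds(arr: np.ndarray, rate: float, seconds: np.ndarray) -> np.ndarray:
    r = int(rate)
    idx = (seconds[:, None] * r + np.arange(r)[None, :]).reshape(-1)
    idx = idx[idx < len(arr)]
    return arr[idx]


def read_wesad_cohort(root: str | Path) -> list[RawSession]:
    """Read every ``S*/S*.pkl`` subject bundle under ``root``."""
    root = Path(root)
    paths = sorted(root.glob("S*/S*.pkl"))
    if not paths:
        raise FileNotFoundError(f"no WESAD subject bundles under {root}")
    return [read_wesad_subject(p) for p in paths]
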