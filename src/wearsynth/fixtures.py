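"""Seeded generation of Empatica-E4-like wearable stress cohorts.

The generator emulates the statistical structure of a wrist-device lab
stress study: per subject, ~36 minutes of six-channel data (three-axis
acceleration, blood volume pulse, electrodermal activity, skin
temperature) recorded at the device's native rates, with a per-second
affect label track (neutral / stress / amusement).  Stress raises EDA,
lowers skin temperature, and speeds up the BVP oscillation; ACC is
zero-mean noise.  The point is a controllable, fully deterministic
test-bed for the preparation / GAN / classification pipeline — not a
physiological simulator.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: canonical channel order used across the whole package
SIGNALS = ("acc_x", "acc_y", "acc_z", "bvp", "eda", "temp")

#: documented Empatica E4 native sampling rates (Hz)
DEFAULT_RATES = {
    "acc_x": 32.0,
    "acc_y": 32.0,
    "acc_z": 32.0,
    "bvp": 64.0,
    "eda": 4.0,
    "temp": 4.0,
}

LABEL_NEUTRAL, LABEL_STRESS, LABEL_AMUSEMENT = 0, 1, 2


class FixtureError(ValueError):
    """Invalid fixture specification; the message names the field."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cohort.

    Effect sizes are expressed in physical units (µS for EDA, °C for
    TEMP, Hz for the BVP oscillation) so their sign and rough magnitude
    can be read against the stress-physiology literature: EDA up,
    temperature down, heart rate (hence BVP frequency) up under stress.
    """

    duration_s: int = 2160
    stress_fraction: float = 0.30
    amusement_share: float = 0.10
    native_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    eda_baseline: float = 2.0
    eda_shift: float = 2.0
    temp_baseline: float = 33.5
    temp_shift: float = -0.8
    bvp_freq_nonstress: float = 1.1
    bvp_freq_stress: float = 1.5
    bvp_amplitude: float = 1.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "acc_x": 0.15,
            "acc_y": 0.15,
            "acc_z": 0.15,
            "bvp": 0.30,
            "eda": 0.25,
            "temp": 0.10,
        }
    )
    ar_coeff: float = 0.9
    min_stress_blocks: int = 2
    max_stress_blocks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 120:
            raise FixtureError(f"duration_s must be >= 120, got {self.duration_s}")
        if not 0.0 < self.stress_fraction < 1.0:
            raise FixtureError(
                f"stress_fraction must be in (0, 1), got {self.stress_fraction}"
            )
        if not 0.0 <= self.amusement_share < 1.0:
            raise FixtureError(
                f"amusement_share must be in [0, 1), got {self.amusement_share}"
            )
        for name in SIGNALS:
            if name not in self.native_rates:
                raise FixtureError(f"native_rates missing signal {name!r}")
            if self.native_rates[name] < 1.0:
                raise FixtureError(
                    f"native_rates[{name!r}] must be >= 1 Hz, "
                    f"got {self.native_rates[name]}"
                )
        if self.eda_shift < 0:
            raise FixtureError(f"eda_shift must be >= 0, got {self.eda_shift}")
        if self.temp_shift > 0:
            raise FixtureError(f"temp_shift must be <= 0, got {self.temp_shift}")
        if self.bvp_freq_stress <= self.bvp_freq_nonstress:
            raise FixtureError(
                "bvp_freq_stress must exceed bvp_freq_nonstress, got "
                f"{self.bvp_freq_stress} <= {self.bvp_freq_nonstress}"
            )
        if not 0 < self.min_stress_blocks <= self.max_stress_blocks:
            raise FixtureError(
                "stress block bounds must satisfy 0 < min <= max, got "
                f"({self.min_stress_blocks}, {self.max_stress_blocks})"
            )
        if not 0.0 <= self.ar_coeff < 1.0:
            raise FixtureError(f"ar_coeff must be in [0, 1), got {self.ar_coeff}")


@dataclass
class RawSession:
    """One subject's multi-rate recording plus a per-second label track."""

    subject_id: str
    signals: dict[str, np.ndarray]
    rates: dict[str, float]
    labels: np.ndarray  # shape (duration_s,), codes {0, 1, 2}

    @property
    def duration_s(self) -> int:
        return int(len(self.labels))


def _subject_rng(spec: FixtureSpec, subject_id: str) -> np.random.Generator:
    # crc32 gives a stable cross-run hash of the id (builtin hash() is salted)
    return np.random.default_rng(
        [spec.seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode("utf-8"))]
    )


def _stress_schedule(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-second 0/1 stress indicator with 2–4 contiguous stress blocks.

    Total stress seconds are fixed to round(stress_fraction * duration)
    and split over the blocks; gaps are drawn uniformly, so realized
    fraction is exact up to rounding.
    """
    T = spec.duration_s
    total = int(round(spec.stress_fraction * T))
    n_blocks = int(rng.integers(spec.min_stress_blocks, spec.max_stress_blocks + 1))
    n_blocks = max(1, min(n_blocks, total))
    # split `total` stress seconds into n_blocks parts of >= 1 s
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_blocks - 1, replace=False))
    lengths = np.diff(np.concatenate([[0], cuts, [total]])).astype(int)
    # distribute remaining non-stress seconds into n_blocks + 1 gaps
    free = T - total
    gap_cuts = np.sort(rng.integers(0, free + 1, size=n_blocks))
    gaps = np.diff(np.concatenate([[0], gap_cuts, [free]])).astype(int)
    track = np.zeros(T, dtype=np.int64)
    pos = gaps[0]
    for blen, gap in zip(lengths, gaps[1:]):
        track[pos : pos + blen] = 1
        pos += blen + gap
    return track


def _ar1_noise(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """x_t = rho * x_{t-1} + sqrt(1 - rho^2) * eps_t with x_0 = eps_0."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    eps = rng.standard_normal(n) * sd
    scale = np.sqrt(1.0 - rho * rho)
    out, _ = lfilter([1.0], [1.0, -rho], scale * eps,
                     zi=np.array([eps[0] * (1.0 - scale)]))
    return out


def generate_session(spec: FixtureSpec, subject_id: str) -> RawSession:
    """Generate one subject deterministically from (spec.seed, subject_id)."""
    rng = _subject_rng(spec, subject_id)
    stress = _stress_schedule(spec, rng)

    labels = np.where(stress == 1, LABEL_STRESS, LABEL_NEUTRAL)
    nonstress_idx = np.flatnonzero(stress == 0)
    n_amuse = int(round(spec.amusement_share * len(nonstress_idx)))
    if n_amuse > 0:
        amuse = rng.choice(nonstress_idx, size=n_amuse, replace=False)
        labels[amuse] = LABEL_AMUSEMENT

    signals: dict[str, np.ndarray] = {}
    for name in SIGNALS:
        rate = spec.native_rates[name]
        n = int(round(rate * spec.duration_s))
        # stress indicator sampled at the native rate
        sec_idx = np.minimum((np.arange(n) / rate).astype(int), spec.duration_s - 1)
        s = stress[sec_idx].astype(float)
        noise = _ar1_noise(n, spec.noise_sd[name], spec.ar_coeff, rng)
        if name == "eda":
            base = spec.eda_baseline + spec.eda_shift * s
            signals[name] = base + noise
        elif name == "temp":
            base = spec.temp_baseline + spec.temp_shift * s
            signals[name] = base + noise
        elif name == "bvp":
            freq = np.where(s > 0, spec.bvp_freq_stress, spec.bvp_freq_nonstress)
            phase = 2.0 * np.pi * np.cumsum(freq) / rate
            signals[name] = spec.bvp_amplitude * np.sin(phase) + noise
        else:  # acc_*: zero-mean movement noise
            signals[name] = noise

    return RawSession(
        subject_id=subject_id,
        signals=signals,
        rates=dict(spec.native_rates),
        labels=labels.astype(np.int64),
    )


def generate_cohort(spec: FixtureSpec, n_subjects: int) -> list[RawSession]:
    """Generate ``n_subjects`` independent subjects, ids ``S01`` .. ``Snn``."""
    if n_subjects < 1:
        raise FixtureError(f"n_subjects must be >= 1, got {n_subjects}")
    return [
        generate_session(spec, f"S{i + 1:02d}") for i in range(n_subjects)
    ]


# ---------------------------------------------------------------------------
# cohort directory I/O (one CSV per subject per signal + labels + manifest)

def write_cohort(sessions: list[RawSession], out_dir: str | Path,
                 spec: FixtureSpec | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ses in sessions:
        sdir = out / ses.subject_id
        sdir.mkdir(exist_ok=True)
        for name in SIGNALS:
            arr = ses.signals[name]
            t = np.arange(len(arr)) / ses.rates[name]
            np.savetxt(
                sdir / f"{name}.csv",
                np.column_stack([t, arr]),
                delimiter=",",
                header="time_s,value",
                comments="",
                fmt="%.6f",
            )
        np.savetxt(
            sdir / "labels.csv",
            np.column_stack([np.arange(ses.duration_s), ses.labels]),
            delimiter=",",
            header="second,label",
            comments="",
            fmt="%d",
        )
    manifest = {
        "subjects": [s.subject_id for s in sessions],
        "rates": sessions[0].rates if sessions else {},
        "spec": dataclasses.asdict(spec) if spec is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(in_dir: str | Path) -> list[RawSession]:
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    sessions = []
    for sid in manifest["subjects"]:
        sdir = root / sid
        labels = np.loadtxt(sdir / "labels.csv", delimiter=",", skiprows=1)[:, 1]
        signals, rates = {}, {}
        for name in SIGNALS:
            data = np.loadtxt(sdir / f"{name}.csv", delimiter=",", skiprows=1)
            signals[name] = data[:, 1]
            rates[name] = float(manifest["rates"][name])
        sessions.append(
            RawSession(
                subject_id=sid,
                signals=signals,
                rates=rates,
                labels=labels.astype(np.int64),
            )
        )
    return sessions
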