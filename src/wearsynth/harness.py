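"""Leave-one-subject-out evaluation of real, synthetic and augmented
training strategies, plus the linear spectral-power baseline.

Strategies: ORIG trains on the fold's real windows only; TSTR (train
synthetic, test real) trains on GAN output only; AUGM concatenates the
fold's real windows with GAN output.  The GAN of a fold never sees the
fold's test subject, test sets are always real, every fold × repeat is
seeded, and aggregate scores are unweighted means over folds, then
repeats.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .classifiers import Metrics, compute_metrics, evaluate, make_classifier
from .dp import PrivacySpec
from .fixtures import SIGNALS, RawSession
from .gan import ConditionalGan, SyntheticCohort, synthesize_subjects
from .prep import WindowSet, minmax_normalize, prepare_cohort, resample_to_1hz, slice_windows
from .quality import avg_pct_change
from .spectra import SpectraConfig, SpectrumSet, featurize_windows, spectral_power

__all__ = [
    "ExperimentPlan", "RunReport", "HarnessError", "loso_folds",
    "compose_training", "run_experiment", "baseline_signal_sweep",
]


class HarnessError(ValueError):
    pass


STRATEGIES = ("ORIG", "TSTR", "AUGM")


@dataclass
class ExperimentPlan:
    """What to run: strategy, model, GAN and privacy settings, repeats."""

    strategy: str = "ORIG"
    classifier: str = "cnn"
    classifier_params: dict = field(default_factory=dict)
    gan_params: dict = field(default_factory=dict)
    synth_subjects: int = 15
    stress_share: float = 0.30
    epsilon: float = float("inf")
    gan_stride_s: int = 30
    eval_stride_s: int = 60
    repeats: int = 10
    base_seed: int = 0
    shared_gan: bool = False  # non-LOSO-conform shortcut for cheap smoke runs

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise HarnessError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if self.repeats < 1:
            raise HarnessError(f"repeats must be >= 1, got {self.repeats}")
        if self.synth_subjects < 1:
            raise HarnessError(f"synth_subjects must be >= 1")


@dataclass
class RunReport:
    """Per-fold metrics for every repeat plus the aggregate summary."""

    per_fold: list[dict]          # {repeat, subject, metrics: Metrics, seed}
    aggregate: dict               # mean/sd of f1, precision, recall, accuracy
    plan: ExperimentPlan | None = None

    def recompute_aggregate(self) -> dict:
        return _aggregate(self.per_fold)


def _aggregate(per_fold: list[dict]) -> dict:
    by_repeat: dict[int, list[Metrics]] = {}
    for row in per_fold:
        by_repeat.setdefault(row["repeat"], []).append(row["metrics"])
    repeat_means = {
        name: [float(np.mean([getattr(m, name) for m in ms]))
               for ms in by_repeat.values()]
        for name in ("f1", "precision", "recall", "accuracy")
    }
    return {
        name: {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        for name, vals in repeat_means.items()
    }


def loso_folds(subject_ids: list[str]) -> list[tuple[str, list[str]]]:
    """One fold per subject: (test subject, the remaining train subjects)."""
    ids = list(subject_ids)
    if len(ids) < 2:
        raise HarnessError("LOSO needs at least 2 subjects")
    if len(set(ids)) != len(ids):
        raise HarnessError("duplicate subject ids")
    return [(sid, [s for s in ids if s != sid]) for sid in ids]


def compose_training(fold_windows: WindowSet, strategy: str,
                     synth: SyntheticCohort | None) -> WindowSet:
    """Assemble a strategy's training WindowSet from real and synthetic
    parts; per-window subject tags are retained for leakage audits."""
    if strategy == "ORIG":
        return fold_windows
    if synth is None:
        raise HarnessError(f"strategy {strategy} requires a synthetic cohort")
    if strategy == "TSTR":
        return synth.all_windows()
    if strategy == "AUGM":
        return WindowSet.concat([fold_windows, synth.all_windows()])
    raise HarnessError(f"unknown strategy {strategy!r}")


def _fold_seed(base_seed: int, subject_id: str, repeat: int) -> int:
    return int((base_seed * 1_000_003 + zlib.crc32(subject_id.encode())
                + 7919 * repeat) % (2**31 - 1))


def run_experiment(plan: ExperimentPlan, cohort: list[RawSession],
                   spectra_cfg: SpectraConfig | None = None) -> RunReport:
    """Full LOSO × repeats evaluation of one experiment plan.

    Per fold: normalize with the training subjects' statistics, train
    the fold GAN on stride-``gan_stride_s`` windows (TSTR/AUGM only),
    synthesize, compose the training set, featurize, train the
    classifier (privately when ε is finite) and evaluate on the held-out
    subject's real stride-``eval_stride_s`` windows.
    """
    ids = [s.subject_id for s in cohort]
    folds = loso_folds(ids)
    by_id = {s.subject_id: s for s in cohort}
    aligned = {sid: resample_to_1hz(ses) for sid, ses in by_id.items()}
    cfg = spectra_cfg or SpectraConfig()
    per_fold: list[dict] = []

    for repeat in range(plan.repeats):
        shared_gan_model = None
        for test_id, train_ids in folds:
            seed = _fold_seed(plan.base_seed, test_id, repeat)
            train_aligned, stats = minmax_normalize(
                [aligned[sid] for sid in train_ids])
            test_aligned, _ = minmax_normalize([aligned[test_id]], stats)
            real_train = WindowSet.concat(
                [slice_windows(s, stride_s=plan.eval_stride_s)
                 for s in train_aligned])
            test_ws = slice_windows(test_aligned[0], stride_s=plan.eval_stride_s)

            synth = None
            if plan.strategy in ("TSTR", "AUGM"):
                if plan.shared_gan and shared_gan_model is not None:
                    gan = shared_gan_model
                else:
                    gan_train = WindowSet.concat(
                        [slice_windows(s, stride_s=plan.gan_stride_s)
                         for s in train_aligned])
                    gan_params = dict(plan.gan_params)
                    if np.isfinite(plan.epsilon):
                        n_unique, mult = _sliding_counts(
                            train_aligned, plan.gan_stride_s)
                        gan_params.setdefault("privacy", PrivacySpec(
                            epsilon=plan.epsilon,
                            unique_n=n_unique,
                            effective_epochs=mult * gan_params.get("epochs", 420),
                        ))
                    gan = ConditionalGan(random_state=seed, **gan_params)
                    gan.fit(gan_train.windows, gan_train.labels)
                    if plan.shared_gan:
                        shared_gan_model = gan
                synth = synthesize_subjects(
                    gan, plan.synth_subjects, stress_share=plan.stress_share,
                    random_state=seed + 1)

            training = compose_training(real_train, plan.strategy, synth)
            train_feats = featurize_windows(training, cfg)
            test_feats = featurize_windows(test_ws, cfg)

            clf_params = dict(plan.classifier_params)
            if np.isfinite(plan.epsilon) and plan.strategy in ("ORIG", "AUGM"):
                # real windows enter classifier training → privatize it
                clf_params.setdefault("privacy", PrivacySpec(
                    epsilon=plan.epsilon, unique_n=len(training),
                    effective_epochs=clf_params.get("epochs"),
                ))
            clf = make_classifier(plan.classifier, random_state=seed,
                                  **clf_params)
            clf.fit(train_feats.features, train_feats.labels)
            metrics = evaluate(clf, test_feats)
            per_fold.append({"repeat": repeat, "subject": test_id,
                             "metrics": metrics, "seed": seed})
    return RunReport(per_fold=per_fold, aggregate=_aggregate(per_fold), plan=plan)


def _sliding_counts(train_aligned, gan_stride_s: int) -> tuple[int, int]:
    n_sliding = sum(
        (s.data.shape[0] - 60) // gan_stride_s + 1 for s in train_aligned)
    n_unique = sum((s.data.shape[0] - 60) // 60 + 1 for s in train_aligned)
    from .dp import sliding_window_accounting
    return sliding_window_accounting(max(n_sliding, n_unique), n_unique)


def baseline_signal_sweep(power: np.ndarray, subjects: np.ndarray,
                          labels: np.ndarray) -> dict:
    """Logistic-regression baseline over all 63 signal subsets.

    ``power`` is the (N, 6) per-window mean spectral power (see
    :func:`wearsynth.spectra.spectral_power`).  Each non-empty subset of
    the six signals is evaluated in the LOSO setting with a linear
    logistic model; returns per-subset mean F1, the coefficients of the
    all-signal model, and the per-signal stress/non-stress average
    percentage change of mean spectral power.
    """
    power = np.asarray(power, dtype=float)
    subjects = np.asarray(subjects)
    labels = np.asarray(labels, dtype=int)
    ids = sorted(set(subjects.tolist()))
    if len(ids) < 2:
        raise HarnessError("baseline sweep needs at least 2 subjects")
    folds = loso_folds(ids)

    rows = []
    for r in range(1, len(SIGNALS) + 1):
        for combo in itertools.combinations(range(len(SIGNALS)), r):
            f1s, skipped = [], 0
            for test_id, _train in folds:
                tr = subjects != test_id
                te = ~tr
                if len(np.unique(labels[tr])) < 2:
                    skipped += 1
                    continue
                clf = LogisticRegression(max_iter=1000)
                clf.fit(power[tr][:, combo], labels[tr])
                pred = clf.predict(power[te][:, combo])
                f1s.append(compute_metrics(labels[te], pred).f1)
            rows.append({
                "signals": tuple(SIGNALS[i] for i in combo),
                "mean_f1": float(np.mean(f1s)) if f1s else float("nan"),
                "folds_skipped": skipped,
            })
    rows.sort(key=lambda r: -r["mean_f1"])

    full = LogisticRegression(max_iter=1000).fit(power, labels)
    pct_change = {}
    for i, name in enumerate(SIGNALS):
        a = float(power[labels == 1, i].mean())
        b = float(power[labels == 0, i].mean())
        pct_change[name] = avg_pct_change(a, b)
    return {
        "table": rows,
        "coefficients": dict(zip(SIGNALS, full.coef_[0].tolist())),
        "pct_change": pct_change,
    }


def baseline_from_cohort(cohort: list[RawSession], stride_s: int = 60) -> dict:
    """Convenience wrapper: prepare a cohort and run the baseline sweep."""
    ws, _ = prepare_cohort(cohort, stride_s=stride_s)
    feats = featurize_windows(ws)
    return baseline_signal_sweep(spectral_power(feats.features), ws.subjects,
                                 ws.labels)
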