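"""Quality suite: correlations, C2ST calibration, embeddings, densities."""

import numpy as np
import pytest

from wearsynth.fixtures import SIGNALS, FixtureSpec, generate_cohort
from wearsynth.prep import WindowSet, prepare_cohort
from wearsynth.quality import (
    QualityError,
    avg_pct_change,
    c2st,
    correlation_with_p,
    density_compare,
    embed_2d,
)

EDA, TEMP = SIGNALS.index("eda"), SIGNALS.index("temp")
LABEL = 6


def _windowset(windows, labels):
    windows = np.asarray(windows, dtype=float)
    return WindowSet(windows=windows, labels=np.asarray(labels),
                     subjects=np.array(["S"] * len(windows), dtype=object))


def _make_corr_windows(x, y):
    """Two perfectly correlated channels, embedded in 60-s windows."""
    n = len(x)
    w = np.zeros((n, 60, 6))
    w[:, :, 0] = np.asarray(x)[:, None]
    w[:, :, 1] = np.asarray(y)[:, None]
    labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
    return _windowset(w, labels)


class TestCorrelation:
    def test_diagonal_is_one(self, small_windows):
        rep = correlation_with_p(small_windows)
        np.testing.assert_allclose(np.diag(rep.r), 1.0)
        assert np.all(np.abs(rep.r) <= 1.0 + 1e-12)
        assert rep.r.shape == rep.p.shape == (7, 7)

    def test_hand_computed_perfect_correlations(self):
        ws = _make_corr_windows([1, 2, 3, 4], [2, 4, 6, 8])
        assert correlation_with_p(ws).r[0, 1] == pytest.approx(1.0)
        ws = _make_corr_windows([1, 2, 3, 4], [8, 6, 4, 2])
        assert correlation_with_p(ws).r[0, 1] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self, rng):
        n = 40
        w = rng.random((n, 60, 6))
        ws = _windowset(w, rng.integers(0, 2, n))
        rep = correlation_with_p(ws)
        x = w.reshape(-1, 6)[:, 0]
        y = w.reshape(-1, 6)[:, 1]
        r_direct = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2)))
        assert rep.r[0, 1] == pytest.approx(r_direct, abs=1e-10)

    def test_fixture_effect_signs(self, small_windows):
        rep = correlation_with_p(small_windows)
        assert rep.r[EDA, LABEL] > 0
        assert rep.r[TEMP, LABEL] < 0
        assert rep.p[EDA, LABEL] < 0.01

    def test_degenerate_column_flagged(self):
        w = np.random.default_rng(0).random((10, 60, 6))
        w[:, :, 2] = 0.5
        ws = _windowset(w, np.array([0, 1] * 5))
        rep = correlation_with_p(ws)
        assert SIGNALS[2] in rep.degenerate
        assert rep.r[2, LABEL] == 0.0 and rep.p[2, LABEL] == 1.0


class TestC2ST:
    def test_separable_sets_fully_distinguished(self):
        real = _windowset(np.full((40, 60, 6), 0.1), np.zeros(40))
        fake = _windowset(np.full((40, 60, 6), 0.9), np.zeros(40))
        res = c2st(real, fake, seed=0)
        assert res.accuracy > 0.95

    def test_null_calibration_same_distribution(self, rng):
        accs = []
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            a = _windowset(r.random((60, 60, 6)), r.integers(0, 2, 60))
            b = _windowset(r.random((60, 60, 6)), r.integers(0, 2, 60))
            accs.append(c2st(a, b, seed=seed).accuracy)
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_permutation_null(self, rng):
        """Shuffling the real/fake assignment before training destroys
        any signal even for separable pools."""
        vals = np.concatenate([np.full(30, 0.1), np.full(30, 0.9)])
        rng.shuffle(vals)
        a = _windowset(np.tile(vals[:30, None, None], (1, 60, 6)), np.zeros(30))
        b = _windowset(np.tile(vals[30:, None, None], (1, 60, 6)), np.zeros(30))
        res = c2st(a, b, seed=1)
        assert 0.2 <= res.accuracy <= 0.8

    def test_too_small_input_rejected(self):
        tiny = _windowset(np.zeros((3, 60, 6)), np.zeros(3))
        with pytest.raises(QualityError):
            c2st(tiny, tiny)

    def test_strata_reported(self, small_windows):
        res = c2st(small_windows, small_windows, seed=0)
        assert res.accuracy_stress is not None
        assert 0.0 <= res.accuracy <= 1.0


class TestEmbed:
    def test_identical_sets_project_identically(self, small_windows):
        cr, cs, loadings = embed_2d(small_windows, small_windows, "pca", seed=0)
        np.testing.assert_allclose(cr, cs)
        assert loadings.shape == (2, 6)
        assert cr.shape[1] == 2

    def test_rank_one_data_concentrates_first_component(self, rng):
        w = np.zeros((30, 60, 6))
        w[:, :, EDA] = rng.random(30)[:, None]
        ws = _windowset(w, rng.integers(0, 2, 30))
        _, _, loadings = embed_2d(ws, ws, "pca", seed=0)
        assert loadings[0, EDA] == pytest.approx(1.0, abs=1e-8)
        assert np.all(loadings[0, [i for i in range(6) if i != EDA]] < 1e-8)

    def test_tsne_returns_two_dims(self, small_windows):
        sub = small_windows.subset(np.arange(len(small_windows)) < 25)
        cr, cs, loadings = embed_2d(sub, sub, "tsne", seed=0)
        assert cr.shape[1] == 2 and loadings is None

    def test_unknown_method_rejected(self, small_windows):
        with pytest.raises(QualityError):
            embed_2d(small_windows, small_windows, "umap")


class TestDensity:
    def test_identical_inputs_identical_densities(self, small_windows):
        out = density_compare(small_windows, small_windows, "eda")
        for lab in out["real"]:
            np.testing.assert_allclose(out["real"][lab], out["synth"][lab])

    def test_densities_integrate_to_one(self, small_windows):
        out = density_compare(small_windows, small_windows, "temp", bins=40)
        width = 1.0 / 40
        for side in ("real", "synth"):
            for density in out[side].values():
                assert np.sum(density) * width == pytest.approx(1.0)

    def test_fixture_stress_eda_mass_shifted_right(self, small_windows):
        out = density_compare(small_windows, small_windows, "eda")
        edges = out["edges"]
        mids = 0.5 * (edges[:-1] + edges[1:])
        mean_stress = np.sum(mids * out["real"][1]) / np.sum(out["real"][1])
        mean_calm = np.sum(mids * out["real"][0]) / np.sum(out["real"][0])
        assert mean_stress > mean_calm

    def test_empty_stratum_flagged(self):
        w = np.random.default_rng(0).random((10, 60, 6))
        all_calm = _windowset(w, np.zeros(10))
        out = density_compare(all_calm, all_calm, "eda")
        assert "real/1" in out["missing"]


class TestAvgPctChange:
    def test_equal_values_zero(self):
        assert avg_pct_change(3.0, 3.0) == 0.0

    def test_hand_computed_example(self):
        assert avg_pct_change(3.0, 1.0) == pytest.approx(100.0)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.random(2) + 0.1
            assert avg_pct_change(a, b) == avg_pct_change(b, a)

    def test_zero_sum_rejected(self):
        with pytest.raises(QualityError):
            avg_pct_change(1.0, -1.0)
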