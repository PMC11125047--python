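"""Privacy machinery: clipping, δ rule, accountant, noise calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from wearsynth.dp import (
    AccountantState,
    DPError,
    PrivacySpec,
    calibrate_noise,
    clip_per_example,
    epsilon_spent,
    select_delta,
    sliding_window_accounting,
)
from wearsynth.fixtures import FixtureSpec, generate_cohort
from wearsynth.prep import prepare_cohort


class TestClipping:
    def test_small_gradient_untouched(self):
        g = np.array([[0.3, 0.4]])  # norm 0.5
        np.testing.assert_allclose(clip_per_example(g, 1.0), g)

    def test_large_gradient_scaled_to_bound(self):
        g = np.array([[0.0, 4.0]])
        out = clip_per_example(g, 1.0)
        assert np.linalg.norm(out) == pytest.approx(1.0)
        np.testing.assert_allclose(out, g * 0.25)

    def test_random_gradients_norm_audit(self, rng):
        g = rng.standard_normal((50, 30)) * 3.0
        out = clip_per_example(g, 1.0)
        norms = np.linalg.norm(out, axis=1)
        assert np.all(norms <= 1.0 + 1e-9)

    def test_multi_array_per_example_clipping(self, rng):
        grads = [[rng.standard_normal((4, 4)), rng.standard_normal(4)]
                 for _ in range(5)]
        out = clip_per_example(grads, 0.7)
        for ex in out:
            total = math.sqrt(sum(float(np.sum(a * a)) for a in ex))
            assert total <= 0.7 + 1e-9


class TestSlidingAccounting:
    def test_doubled_sampling_from_30s_slide(self):
        assert sliding_window_accounting(1000, 496) == (496, 2)

    def test_no_sliding_multiplier_one(self):
        assert sliding_window_accounting(496, 496) == (496, 1)

    def test_rejects_sliding_below_unique(self):
        with pytest.raises(DPError):
            sliding_window_accounting(100, 496)

    def test_fixture_cohort_counts_match_direct_enumeration(self, small_cohort):
        ws30, _ = prepare_cohort(small_cohort, stride_s=30)
        ws60, _ = prepare_cohort(small_cohort, stride_s=60)
        n_subjects = len(small_cohort)
        # per subject: stride 30 gives 2*unique - 1 windows
        assert len(ws30) == 2 * len(ws60) - n_subjects
        unique_n, mult = sliding_window_accounting(len(ws30), len(ws60))
        assert (unique_n, mult) == (len(ws60), 2)


class TestSelectDelta:
    def test_rule_at_496(self):
        assert select_delta(496) == 1e-3

    def test_small_n(self):
        assert select_delta(5) == 1e-1

    @pytest.mark.parametrize("k", range(1, 9))
    def test_exact_powers_of_ten(self, k):
        # brute-force scan: largest 10^-m strictly below 1/n
        n = 10**k
        candidates = [10.0**-m for m in range(1, 15) if 10.0**-m < 1.0 / n]
        assert select_delta(n) == max(candidates)


def _analytic_gaussian_eps_oracle(sigma, delta):
    """Independent closed-form oracle: grid + bisection on the Gaussian
    mechanism's exact delta(eps) curve."""
    def delta_of(eps):
        return (norm.cdf(0.5 / sigma - eps * sigma)
                - math.exp(eps) * norm.cdf(-0.5 / sigma - eps * sigma))

    lo, hi = 0.0, 200.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if delta_of(mid) > delta:
            lo = mid
        else:
            hi = mid
    return hi


class TestAccountant:
    def test_noise_monotonicity(self):
        e1 = epsilon_spent(1.0, 0.01, 100, 1e-3)
        e2 = epsilon_spent(2.0, 0.01, 100, 1e-3)
        assert e2 < e1

    def test_epsilon_nondecreasing_in_steps(self):
        grid = [10, 100, 1000, 5000]
        eps = [epsilon_spent(1.5, 0.02, s, 1e-3) for s in grid]
        assert all(a <= b + 1e-12 for a, b in zip(eps, eps[1:]))

    def test_subsampling_amplifies_privacy(self):
        full = epsilon_spent(2.0, 1.0, 1, 1e-3)
        sub = epsilon_spent(2.0, 0.1, 1, 1e-3)
        assert sub < full

    def test_single_step_full_batch_matches_gaussian_mechanism(self):
        for sigma in (1.0, 2.0, 5.0):
            mine = epsilon_spent(sigma, 1.0, 1, 1e-3)
            oracle = _analytic_gaussian_eps_oracle(sigma, 1e-3)
            assert mine == pytest.approx(oracle, rel=0.10)

    def test_zero_sigma_is_infinite(self):
        assert math.isinf(epsilon_spent(0.0, 0.5, 10, 1e-3))

    def test_accountant_state_monotone(self):
        acc = AccountantState(sigma=1.5, q=0.05, delta=1e-3)
        assert acc.epsilon == 0.0
        acc.step(100)
        e1 = acc.epsilon
        acc.step(100)
        assert acc.epsilon >= e1 > 0


class TestCalibration:
    def test_round_trip_epsilon_10(self):
        spec = PrivacySpec(epsilon=10.0, delta=1e-3, batch_size=8,
                           unique_n=496, effective_epochs=840)
        sigma = calibrate_noise(spec)
        spent = epsilon_spent(sigma, spec.sampling_rate, spec.steps, spec.delta)
        assert spent <= 10.0
        assert spent > 10.0 * 0.99  # smallest sigma: budget nearly used

    def test_sigma_increases_for_stricter_budget(self):
        kw = dict(delta=1e-3, batch_size=8, unique_n=496, effective_epochs=840)
        s10 = calibrate_noise(PrivacySpec(epsilon=10.0, **kw))
        s1 = calibrate_noise(PrivacySpec(epsilon=1.0, **kw))
        assert s1 > s10

    def test_nonprivate_passthrough(self):
        assert calibrate_noise(PrivacySpec(epsilon=math.inf)) == 0.0

    def test_unreachable_target_raises(self):
        spec = PrivacySpec(epsilon=1e-6, delta=1e-3, batch_size=8,
                           unique_n=496, effective_epochs=840)
        with pytest.raises(DPError, match="unreachable"):
            calibrate_noise(spec)


class TestPrivacySpec:
    def test_delta_must_beat_one_over_n(self):
        with pytest.raises(DPError, match="delta"):
            PrivacySpec(epsilon=1.0, delta=1e-2, unique_n=496)

    def test_defaults_match_private_training_schedule(self):
        spec = PrivacySpec(epsilon=10.0, unique_n=496, effective_epochs=840)
        assert spec.delta == 1e-3
        assert spec.clip_norm == 1.0
        assert spec.batch_size == spec.microbatches == 8
        assert spec.steps == 840 * 496 // 8

    @given(st.floats(min_value=-5, max_value=0))
    @settings(max_examples=10, deadline=None)
    def test_nonpositive_epsilon_rejected(self, eps):
        with pytest.raises(DPError):
            PrivacySpec(epsilon=eps)
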