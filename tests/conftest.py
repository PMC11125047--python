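import numpy as np
import pytest

from wearsynth.fixtures import FixtureSpec, generate_cohort
from wearsynth.prep import prepare_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Five fixture subjects at the default study conditions."""
    return generate_cohort(FixtureSpec(seed=5), 5)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    """Prepared stride-60 windows of the small cohort."""
    ws, stats = prepare_cohort(small_cohort, stride_s=60)
    return ws


@pytest.fixture(scope="session")
def sliding_windows(small_cohort):
    ws, stats = prepare_cohort(small_cohort, stride_s=30)
    return ws


@pytest.fixture
def rng():
    return np.random.default_rng(0)
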