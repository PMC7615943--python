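import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radrank as rr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> rr.PhantomSpec:
    """A compact test–retest phantom spec used across the suite."""
    return rr.PhantomSpec(
        n_cases=5,
        grid_shape=(24, 24, 24),
        lesion_semiaxes_mm=(7.0, 6.0, 5.0),
        retest_noise_sd_hu=5.0,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec) -> rr.Cohort:
    return rr.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def demo_scan(small_cohort):
    """One (volume, mask) pair for single-ROI tests."""
    _, vol, mask = small_cohort.cases[0].scans[0]
    return vol, mask


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240612)
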