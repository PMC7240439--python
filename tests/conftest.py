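import numpy as np
import pytest

from wearvalid import generate_cohort, uniform_truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def identity_cohort():
    """Noiseless cohort: every device reading equals the criterion exactly."""
    truth = uniform_truth(
        "hr", devices=("perfect",), error_cv_pct=0.0, bias_std=0.0, seed=7
    )
    return generate_cohort(truth)


@pytest.fixture
def noisy_truth():
    """One device with 5% multiplicative error and no bias, study-sized cohort."""
    return uniform_truth("hr", devices=("dev",), error_cv_pct=5.0, bias_std=0.0, seed=11)


@pytest.fixture
def noisy_cohort(noisy_truth):
    return generate_cohort(noisy_truth)
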