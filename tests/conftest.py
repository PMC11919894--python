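import numpy as np
import pytest

from pediscreen.synth import (CohortSpec, generate_record, normal_template,
                              sample_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def clean_record():
    """Noise-free normal record at 60 bpm with simulator ground truth."""
    params = normal_template(60.0)
    params.baseline_noise_sd = 0.0
    return generate_record(params, age_years=10, sex="male", seed=11,
                           record_id="clean60")


@pytest.fixture()
def noisy_record():
    params = normal_template(95.0)
    return generate_record(params, age_years=8, sex="female", seed=12,
                           record_id="noisy95")


@pytest.fixture(scope="session")
def small_cohort():
    """Sixty-record mixed cohort shared across read-only tests."""
    return sample_cohort(CohortSpec(n_records=60, seed=42))
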