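import numpy as np
import pytest

from beatformer import CohortSpec, generate_cohort, preprocess


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_normal_subjects=3, n_chf_subjects=3,
                      beats_per_subject=30, fs=250, master_seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    return preprocess(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
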