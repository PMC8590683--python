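import numpy as np
import pytest

from apneascreen import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small strong-signal cohort shared by model-level unit tests.

    CVHR amplitude 0.3 s (strong), half-hour records: enough segments to
    train on while keeping unit tests fast.
    """
    spec = synthetic.SyntheticCohortSpec(
        n_patients=2,
        n_healthy=2,
        record_duration_s=1800.0,
        cvhr_amp_s=0.3,
        seed=7,
    )
    return spec, synthetic.generate_cohort(spec)
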