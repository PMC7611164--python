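import logging

import numpy as np
import pytest

from ieegnet.io import Recording
from ieegnet.simulate import SynthConfig, make_cohort

# the generator logs extrapolation/coincident-contact warnings freely in tests
logging.getLogger("ieegnet").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=512.0, patient_id="p", t0=0.0):
    data = np.asarray(data, dtype=float)
    return Recording(
        patient_id=patient_id,
        channel_ids=[f"C{i}" for i in range(data.shape[0])],
        fs=fs,
        data=data,
        t0=t0,
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small fixed-geometry configuration for fast unit tests."""
    return SynthConfig(
        grid_shape=(6, 6),
        grid_rows_range=None,
        grid_cols_range=None,
        pitch_range_mm=None,
        n_resected_range=None,
        n_resected=12,
        epi_set_size=5,
        fs=256.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    """3 good + 3 poor patients, 30 s each; reused across unit tests."""
    patients, _ = make_cohort(3, 3, tiny_cfg, seed=77, duration_s=30.0)
    return patients
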