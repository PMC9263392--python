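import numpy as np
import pytest

from capeneeg import CApEnParams, CohortConfig, calibrate_knob


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort config: few patients, one-epoch recordings."""
    return CohortConfig(n_control=4, n_tdcs=3, duration_s=16.0, seed=5)


@pytest.fixture(scope="session")
def default_calibration():
    """Knob calibration at the default study conditions (computed once)."""
    return calibrate_knob(CohortConfig(seed=5), params=CApEnParams())


@pytest.fixture
def toy_recording(rng):
    from capeneeg import CANONICAL_LABELS, EEGRecording

    return EEGRecording(
        signal=rng.normal(size=(16, 512)),
        fs=128.0,
        channel_labels=CANONICAL_LABELS,
        condition="closed_eyes",
        patient_id="P000",
    )
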