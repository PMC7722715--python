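import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simulated_low_block():
    """One default-parameter low-certainty block, preprocessed and with
    binocular saccades detected; shared across tests that only read it."""
    from oculorate.preprocess import preprocess_recording
    from oculorate.saccades import detect_in_segment
    from oculorate.synthdata import SimParams, build_schedule, simulate_gaze

    params = SimParams()
    schedule = build_schedule("low_certainty", 20, seed=777)
    rec, truth = simulate_gaze(schedule, params, np.random.default_rng(777))
    segments = preprocess_recording(rec, schedule)
    trials = [(seg, detect_in_segment(seg)) for seg in segments]
    return {
        "params": params,
        "schedule": schedule,
        "recording": rec,
        "truth": truth,
        "trials": trials,
    }
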