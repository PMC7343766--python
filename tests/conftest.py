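import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import crowdgaze as cg

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_recording(
    az_l, el_l=None, az_r=None, el_r=None, fs=50.0, button=None
) -> cg.GazeRecording:
    """Build a recording from arrays; eyes default to copies of az_l/el_l."""
    az_l = np.asarray(az_l, dtype=float)
    n = len(az_l)
    el_l = np.zeros(n) if el_l is None else np.asarray(el_l, dtype=float)
    az_r = az_l.copy() if az_r is None else np.asarray(az_r, dtype=float)
    el_r = el_l.copy() if el_r is None else np.asarray(el_r, dtype=float)
    button = np.zeros(n) if button is None else np.asarray(button, dtype=float)
    return cg.GazeRecording(
        pd.DataFrame(
            {
                "t_s": np.arange(n) / fs,
                "az_l_deg": az_l,
                "el_l_deg": el_l,
                "az_r_deg": az_r,
                "el_r_deg": el_r,
                "button_v": button,
            }
        )
    )


BENCH_SCENARIO = cg.ScenarioSpec(
    n_rounds=1, round_duration_s=110.0, lead_in_s=2.0, inter_round_gap_s=2.0
)
BENCH_NOISE = cg.NoiseModel(
    fixation_noise_sd=0.1,
    saccade_amplitude_range=(5.0, 15.0),
    saccade_duration_ms=40.0,
    loss_fraction=0.0,
    drift_rate=0.5,
)


@pytest.fixture(scope="session")
def bench_sim():
    """~2-min clean recording: noise sd 0.1 deg, saccades >= 5 deg, no loss."""
    return cg.simulate_recording(BENCH_SCENARIO, BENCH_NOISE, seed=0)


@pytest.fixture(scope="session")
def bench_classified(bench_sim):
    recording, truth = bench_sim
    fixations, thresholds, velocity = cg.detect_fixations(recording)
    return recording, truth, fixations, thresholds, velocity


@pytest.fixture(scope="session")
def default_sim():
    """Full two-round default scenario with realistic noise and loss."""
    return cg.simulate_recording(seed=11)
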