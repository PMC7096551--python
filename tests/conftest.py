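"""Shared fixtures: simulated profiles and the trained benchmark."""

import numpy as np
import pytest

from imustep.cli import run_pipeline_experiment
from imustep.synthetic import GaitSimSpec, simulate_recording


@pytest.fixture(scope="session")
def sim_ten_steps():
    """One clean profile with exactly 10 steps (generator seed 42)."""
    spec = GaitSimSpec(steps_min=10, steps_max=10, seed=42)
    return simulate_recording(spec, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def benchmark_run():
    """The default 20-profile benchmark experiment at seed 1.

    Returns (metrics_frame, delays_frame, suite, classifier); simulation,
    training, detection and scoring all happen once per session.
    """
    return run_pipeline_experiment(seed=1)


@pytest.fixture(scope="session")
def trained_classifier(benchmark_run):
    return benchmark_run[3]


def make_constant_recording(n=600, value=9.81, rate=100.0):
    """A motionless recording: gravity on Acc_Z, all dynamics zero."""
    from imustep.imu_io import ImuRecording

    zeros = np.zeros(n)
    channels = {
        "Acc_X": zeros.copy(), "Acc_Y": zeros.copy(),
        "Acc_Z": np.full(n, value),
        "FreeAcc_X": zeros.copy(), "FreeAcc_Y": zeros.copy(),
        "FreeAcc_Z": zeros.copy(),
        "Gyr_X": zeros.copy(), "Gyr_Y": zeros.copy(), "Gyr_Z": zeros.copy(),
        "Roll": zeros.copy(), "Pitch": zeros.copy(), "Yaw": zeros.copy(),
        "Quat_W": np.ones(n), "Quat_X": zeros.copy(),
        "Quat_Y": zeros.copy(), "Quat_Z": zeros.copy(),
    }
    return ImuRecording("still", "1", channels, rate)


@pytest.fixture()
def constant_recording():
    return make_constant_recording()
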