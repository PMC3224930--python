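import numpy as np
import pytest

from tonoscan import ScanRecording, StepSegment, SyntheticConfig
from tonoscan.simulate import SubjectModel, simulate_x_scan, simulate_z_scan


def make_step(position_mm=0.0, n=50, rate=500.0, pressure=None, adcw=None, cp=None):
    """Small hand-built step for I/O and container tests."""
    rng = np.random.default_rng(int(position_mm * 1000) + 1)
    return StepSegment(
        position_mm=position_mm,
        pressure=rng.normal(90, 5, n) if pressure is None else pressure,
        adcw=rng.normal(0, 1, n) if adcw is None else adcw,
        contact_pressure=np.full(n, 80.0) if cp is None else cp,
        sampling_rate_hz=rate,
    )


def make_scan(axis="X", n_steps=5, **kwargs):
    step = 0.25 if axis == "X" else 0.125
    return ScanRecording(
        axis=axis,
        steps=[make_step(i * step, **kwargs) for i in range(n_steps)],
        subject_id="T000",
        metadata={"age": 41.0, "SBP": 94.0, "DBP": 48.0},
    )


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(n_subjects=2, seed=0)


@pytest.fixture(scope="session")
def subject():
    return SubjectModel(X0_true_mm=4.0, sigma_true_mm=1.83)


@pytest.fixture(scope="session")
def x_scan(subject, config):
    return simulate_x_scan(subject, config, seed=101)


@pytest.fixture(scope="session")
def z_scan(subject, config):
    return simulate_z_scan(subject, config, seed=202)
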