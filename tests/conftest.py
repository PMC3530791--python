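import numpy as np
import pytest

from gaitrhythm.detect import AccelTrace
from gaitrhythm.simulate import DailyPlan, HourPlan, generate_trace


def walking_plan(
    cadence=110.0,
    amplitude=2.78,
    n_hours=1,
    walking_minutes=60.0,
    noise_sd=0.2,
    artifact_rate=0.0,
    seed=42,
    label="normal",
) -> DailyPlan:
    hours = [HourPlan(walking_minutes, cadence, amplitude, label)] * n_hours
    return DailyPlan(hours=hours, seed=seed, noise_sd=noise_sd,
                     artifact_rate=artifact_rate)


@pytest.fixture(scope="session")
def clean_walk():
    """One noiseless, artifact-free hour of walking at 110 steps/min."""
    plan = walking_plan(noise_sd=0.0)
    plan.jitter_cv = 0.0
    return generate_trace(plan)


@pytest.fixture(scope="session")
def noisy_walk():
    """One hour of walking at default noise and jitter."""
    return generate_trace(walking_plan(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def trace_from_magnitude(mag, dt=0.01, direction=(1.0, 0.0, 0.0)) -> AccelTrace:
    """Wrap a magnitude signal as a trace along a single axis."""
    d = np.asarray(direction, dtype=float)
    return AccelTrace(samples=np.outer(np.asarray(mag, float), d), sample_interval=dt)
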