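import numpy as np
import pytest

from insertmetrics import ForceTrace, MetricConfig


def make_random_traces(n_traces: int = 100, seed: int = 20140715) -> list[ForceTrace]:
    """Fixed-seed random traces mixing regular/irregular sampling and scales.

    Random walks reflected at zero, with scales chosen so that some traces
    cross the 0.1 N threshold and some do not, and durations always exceed
    the 0.1 s sudden-rise grid step.
    """
    rng = np.random.default_rng(seed)
    traces = []
    for _ in range(n_traces):
        n = int(rng.integers(30, 400))
        if rng.random() < 0.5:
            dt = np.full(n - 1, 0.01)
        else:
            dt = 0.005 + rng.exponential(0.01, size=n - 1)
        time = np.concatenate([[0.0], np.cumsum(dt)])
        scale = rng.choice([0.01, 0.05, 0.15, 0.4])
        walk = np.cumsum(rng.normal(0.0, scale / 10.0, size=n))
        force = np.abs(walk + rng.uniform(0.0, scale))
        traces.append(ForceTrace(time=time, force=force))
    return traces


@pytest.fixture(scope="session")
def random_traces() -> list[ForceTrace]:
    return make_random_traces()


@pytest.fixture()
def cfg() -> MetricConfig:
    return MetricConfig()


def constant_trace(value: float, duration: float = 10.0, fs: float = 100.0) -> ForceTrace:
    t = np.arange(int(round(duration * fs)) + 1) / fs
    return ForceTrace(time=t, force=np.full_like(t, value))


def ramp_trace(f_end: float, duration: float, fs: float = 100.0) -> ForceTrace:
    t = np.arange(int(round(duration * fs)) + 1) / fs
    return ForceTrace(time=t, force=f_end * t / duration)
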