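from datetime import time

import numpy as np
import pytest
from hypothesis import settings

from noxim.trace import AnalysisWindow, OximetryTrace

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def window():
    return AnalysisWindow()  # 23:00-05:00, 6 h


def make_trace(
    spo2,
    hr=None,
    valid=None,
    fs=3.0,
    start_clock=time(23, 0),
    participant_id="test",
):
    """Build a trace from raw arrays on a uniform grid starting at the clock."""
    spo2 = np.asarray(spo2, dtype=float)
    n = spo2.size
    return OximetryTrace(
        participant_id=participant_id,
        start_clock=start_clock,
        sample_rate=fs,
        elapsed_s=np.arange(n) / fs,
        spo2=spo2,
        hr=np.full(n, 70.0) if hr is None else np.asarray(hr, dtype=float),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
    )


@pytest.fixture
def trace_factory():
    return make_trace


def random_walk_trace(seed):
    """Quantized random walk with occasional masked samples, <= 500 samples."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 500))
    steps = rng.choice([-2, -1, -1, 0, 0, 0, 1, 1, 2], size=n)
    vals = np.clip(85 + np.cumsum(steps).astype(float), 35, 100)
    valid = rng.random(n) > (0.05 if rng.random() < 0.5 else 0.0)
    return make_trace(vals, valid=valid)
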