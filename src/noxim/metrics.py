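"""Composite nocturnal SpO2 / heart-rate variables for one analysis window.

All statistics are computed over valid samples only. TST80 is reported
against valid time (so TST80 plus time-at-or-above-80 is always 100%);
``valid_fraction`` is carried alongside so the raw-duration alternative is
recoverable. The two halves of the night for dSpO2 are defined by clock time
(first vs second half of the window), not by valid-sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .desat import DetectionParams, detect_events, summarize_events
from .errors import DegenerateTraceError
from .trace import AnalysisWindow, OximetryTrace, hr_valid_mask


@dataclass(frozen=True)
class NightMetrics:
    """Per-participant composite and event-derived nocturnal variables."""

    mean_spo2: float  # %
    min_spo2: float  # %
    morning_spo2: float  # %, mean of the final hour of the window
    delta_spo2: float  # points, second-half mean minus first-half mean
    tst80: float  # % of valid window time with SpO2 < 80
    mean_hr: float  # beats/min
    n_desat: int
    odi: float  # events/h
    mean_desat_duration: float  # s, nan when n_desat == 0
    hypoxic_burden: float  # %.min/h
    valid_fraction: float

    def as_dict(self) -> dict:
        return asdict(self)


FIELDS = list(NightMetrics.__dataclass_fields__)


def _valid(trace: OximetryTrace, sel=None) -> np.ndarray:
    mask = trace.valid if sel is None else (trace.valid & sel)
    vals = trace.spo2[mask]
    if vals.size == 0:
        raise DegenerateTraceError(
            f"trace {trace.participant_id!r}: no valid samples in requested span"
        )
    return vals


def mean_spo2(trace: OximetryTrace) -> float:
    """Arithmetic mean SpO2 over valid samples."""
    return float(_valid(trace).mean())


def min_spo2(trace: OximetryTrace) -> float:
    """Minimum instantaneous SpO2 over valid samples (post-artifact-removal)."""
    return float(_valid(trace).min())


def morning_spo2(trace: OximetryTrace, window: AnalysisWindow) -> float:
    """Mean SpO2 over the final hour of the window, half-open [end-1h, end)."""
    t0 = window.duration_s - 3600.0
    return float(_valid(trace, trace.elapsed_s >= t0 - 1e-9).mean())


def delta_spo2(trace: OximetryTrace, window: AnalysisWindow) -> float:
    """Second-half mean minus first-half mean; positive = overnight increase."""
    mid = window.duration_s / 2.0
    first = _valid(trace, trace.elapsed_s < mid - 1e-9)
    second = _valid(trace, trace.elapsed_s >= mid - 1e-9)
    return float(second.mean() - first.mean())


def tst80(trace: OximetryTrace, window: AnalysisWindow, threshold: float = 80.0) -> float:
    """Percent of valid window time with SpO2 strictly below ``threshold``."""
    vals = _valid(trace)
    return float(100.0 * (vals < threshold).mean())


def mean_hr(trace: OximetryTrace) -> float:
    """Mean heart rate over samples valid in both channels."""
    mask = hr_valid_mask(trace)
    vals = trace.hr[mask]
    if vals.size == 0:
        raise DegenerateTraceError(
            f"trace {trace.participant_id!r}: no valid heart-rate samples"
        )
    return float(vals.mean())


def compute_night_metrics(
    trace: OximetryTrace,
    window: AnalysisWindow = AnalysisWindow(),
    params: DetectionParams = DetectionParams(),
) -> NightMetrics:
    """All per-participant variables from a windowed, artifact-free trace."""
    events = detect_events(trace, params)
    summ = summarize_events(events, window.duration_h)
    return NightMetrics(
        mean_spo2=mean_spo2(trace),
        min_spo2=min_spo2(trace),
        morning_spo2=morning_spo2(trace, window),
        delta_spo2=delta_spo2(trace, window),
        tst80=tst80(trace, window),
        mean_hr=mean_hr(trace),
        n_desat=summ.n_events,
        odi=summ.odi,
        mean_desat_duration=summ.mean_duration_s,
        hypoxic_burden=summ.hypoxic_burden,
        valid_fraction=trace.valid_fraction,
    )
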