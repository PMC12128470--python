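"""Desaturation event detection, per-event hypoxic area, and summaries.

An event is a transient SpO2 excursion below a local baseline satisfying four
criteria: descent rate (mean onset->nadir slope strictly > 0.1 %/s), magnitude
(nadir at least 2 percentage points below baseline), re-saturation pattern
(the event ends at the first sample returning to within 1 point of baseline or
rising 3 points above the nadir, whichever occurs first), and total duration
between 10 and 60 s inclusive. The baseline is the maximum of the preceding
30 s of valid signal, a standard choice that tracks slow drift; events are
confined to contiguous valid segments and never bridge artifact gaps.

The oxygen desaturation index (ODI) is the event count per hour of analysis
window; the hypoxic burden accumulates each event's area between baseline and
signal (%.min) and normalizes per hour (%.min/h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .trace import OximetryTrace


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection thresholds (defaults follow the criteria above)."""

    min_rate: float = 0.1  # %/s, strict
    min_depth: float = 2.0  # percentage points, inclusive
    resat_baseline_margin: float = 1.0  # points below baseline that end an event
    resat_nadir_rise: float = 3.0  # points above nadir that end an event
    min_dur: float = 10.0  # s, inclusive
    max_dur: float = 60.0  # s, inclusive
    baseline_lookback_s: float = 30.0


@dataclass(frozen=True)
class DesaturationEvent:
    onset_index: int
    nadir_index: int
    end_index: int
    baseline_spo2: float
    depth: float  # baseline - nadir, percentage points
    duration_s: float  # onset to re-saturation
    area: float  # %.min between baseline and signal over [onset, end]


@dataclass(frozen=True)
class EventSummary:
    n_events: int
    odi: float  # events / h
    mean_duration_s: float  # nan when n_events == 0
    hypoxic_burden: float  # %.min / h


def event_area(
    onset: int, end: int, baseline: float, trace: OximetryTrace
) -> float:
    """Trapezoidal integral of max(0, baseline - SpO2) over [onset, end], in %.min."""
    seg = trace.spo2[onset : end + 1]
    dep = np.maximum(baseline - seg, 0.0)
    return float(np.trapezoid(dep, dx=1.0 / trace.sample_rate) / 60.0)


def detect_events(
    trace: OximetryTrace, params: DetectionParams = DetectionParams()
) -> list[DesaturationEvent]:
    """Detect desaturation events on an artifact-free windowed trace.

    Returns time-ordered, non-overlapping events; an event-free trace returns
    an empty list. Scanning resumes one sample past each accepted event, so a
    new decline inside a prior event never spawns a separate event.
    """
    k, onset, nadir, end, base = _kernels.detect_scan(
        np.ascontiguousarray(trace.spo2, dtype=np.float64),
        np.ascontiguousarray(trace.valid, dtype=np.bool_),
        float(trace.sample_rate),
        params.min_rate,
        params.min_depth,
        params.resat_baseline_margin,
        params.resat_nadir_rise,
        params.min_dur,
        params.max_dur,
        params.baseline_lookback_s,
    )
    fs = trace.sample_rate
    out = []
    for i in range(k):
        o, m, e, b = int(onset[i]), int(nadir[i]), int(end[i]), float(base[i])
        out.append(
            DesaturationEvent(
                onset_index=o,
                nadir_index=m,
                end_index=e,
                baseline_spo2=b,
                depth=b - float(trace.spo2[m]),
                duration_s=(e - o) / fs,
                area=event_area(o, e, b, trace),
            )
        )
    return out


def summarize_events(
    events: list[DesaturationEvent], analysis_hours: float
) -> EventSummary:
    """ODI, mean event duration and hypoxic burden over ``analysis_hours``."""
    if analysis_hours <= 0:
        raise ValueError("analysis_hours must be positive")
    n = len(events)
    mean_dur = float(np.mean([e.duration_s for e in events])) if n else float("nan")
    burden = sum(e.area for e in events) / analysis_hours
    return EventSummary(
        n_events=n,
        odi=n / analysis_hours,
        mean_duration_s=mean_dur,
        hypoxic_burden=float(burden),
    )


def events_to_table(events: list[DesaturationEvent], fs: float):
    """Per-event ledger rows (onset_s, nadir_s, end_s, baseline, depth, duration_s, area)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "onset_s": [e.onset_index / fs for e in events],
            "nadir_s": [e.nadir_index / fs for e in events],
            "end_s": [e.end_index / fs for e in events],
            "baseline": [e.baseline_spo2 for e in events],
            "depth": [e.depth for e in events],
            "duration_s": [e.duration_s for e in events],
            "area": [e.area for e in events],
        }
    )
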