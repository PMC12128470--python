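"""Raw oximetry traces: ingestion, analysis-window extraction, artifact removal.

A night of fingertip pulse oximetry is a pair of 3 Hz series (SpO2 in %,
heart rate in beats/min) on a uniform time grid. Samples are never dropped:
artifact handling marks samples invalid in a boolean mask, preserving index
positions and timestamps, and invalid samples are excluded from every
downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from datetime import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .errors import (
    CoverageError,
    DegenerateTraceError,
    TraceFormatError,
    TraceStructureError,
)

SPO2_MAX = 100.0  #: values strictly above are artifacts
SPO2_MIN = 30.0  #: values strictly below are artifacts
MAX_STEP = 4.0  #: inter-sample change strictly above this (pct points) is an artifact
HR_MIN = 25.0  #: heart-rate plausibility floor, beats/min
HR_MAX = 250.0  #: heart-rate plausibility ceiling, beats/min


def _clock_to_s(t: time) -> float:
    return t.hour * 3600.0 + t.minute * 60.0 + t.second


def parse_clock(text: str) -> time:
    """Parse 'HH:MM' or 'HH:MM:SS' into a clock time."""
    parts = text.split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"bad clock time {text!r}; expected HH:MM")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    return time(h, m, s)


@dataclass(frozen=True)
class TraceDialect:
    """Maps a delimited trace file onto elapsed-time / SpO2 / HR columns."""

    delimiter: str = ","
    time_col: str = "elapsed_s"
    spo2_col: str = "spo2_pct"
    hr_col: str = "hr_bpm"


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open clock-time window [start, end); a sample stamped exactly at
    ``end`` is excluded. Default is the central 23:00-05:00 stretch of a
    22:00-06:00 recording."""

    start: time = time(23, 0)
    end: time = time(5, 0)

    @property
    def duration_s(self) -> float:
        d = _clock_to_s(self.end) - _clock_to_s(self.start)
        if d <= 0:
            d += 24 * 3600.0
        return d

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


@dataclass
class OximetryTrace:
    """Timestamped SpO2 / heart-rate series with a per-sample validity mask.

    ``elapsed_s`` holds seconds since ``start_clock``; the grid is nominally
    uniform at ``sample_rate`` Hz but is carried explicitly so files with
    gaps remain addressable by time.
    """

    participant_id: str
    start_clock: time
    sample_rate: float
    elapsed_s: np.ndarray
    spo2: np.ndarray
    hr: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.elapsed_s = np.asarray(self.elapsed_s, dtype=float)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.spo2)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.spo2.shape[0]
        if not (self.elapsed_s.shape[0] == self.hr.shape[0] == self.valid.shape[0] == n):
            raise ValueError("elapsed_s, spo2, hr and valid must have identical length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.spo2.shape[0])

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.n_samples else 0.0

    def valid_spo2(self) -> np.ndarray:
        out = self.spo2[self.valid]
        if out.size == 0:
            raise DegenerateTraceError(
                f"trace {self.participant_id!r} has no valid samples"
            )
        return out


def read_trace(
    path: str | Path,
    dialect: TraceDialect = TraceDialect(),
    *,
    participant_id: str | None = None,
    start_clock: time = time(22, 0),
    sample_rate: float | None = None,
) -> OximetryTrace:
    """Read a delimited trace file into an :class:`OximetryTrace`.

    All samples start valid; blank or missing numeric cells become invalid
    samples rather than dropped rows. Non-numeric text in a numeric column is
    a format error naming the offending file line; timestamps must be
    strictly increasing.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc

    missing = [
        c
        for c in (dialect.time_col, dialect.spo2_col, dialect.hr_col)
        if c not in raw.columns
    ]
    if missing:
        raise TraceFormatError(
            f"{path}: missing column(s) {missing}; found {list(raw.columns)}"
        )

    def numeric(col: str, allow_blank: bool) -> np.ndarray:
        s = raw[col].str.strip() if raw[col].dtype == object else raw[col]
        vals = pd.to_numeric(s, errors="coerce")
        blank = s.isna() | (s == "")
        bad = vals.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TraceFormatError(
                f"{path}: unparseable value {s.iloc[row]!r} in column {col!r} "
                f"at line {row + 2}"  # +2: header line plus 1-based numbering
            )
        if not allow_blank and blank.any():
            row = int(np.flatnonzero(blank.to_numpy())[0])
            raise TraceFormatError(f"{path}: blank {col!r} cell at line {row + 2}")
        # exact strtod conversion (to_numeric can be off by an ulp)
        out = np.full(len(s), np.nan)
        keep = ~blank.to_numpy()
        out[keep] = s.to_numpy()[keep].astype(np.float64)
        return out

    t = numeric(dialect.time_col, allow_blank=False)
    spo2 = numeric(dialect.spo2_col, allow_blank=True)
    hr = numeric(dialect.hr_col, allow_blank=True)

    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise TraceStructureError(
            f"{path}: timestamps not strictly increasing at line {row + 2} "
            f"(t={t[row]} after t={t[row - 1]})"
        )

    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(dt)) if dt.size else 3.0

    return OximetryTrace(
        participant_id=participant_id or path.stem,
        start_clock=start_clock,
        sample_rate=float(sample_rate),
        elapsed_s=t,
        spo2=spo2,
        hr=hr,
        valid=np.isfinite(spo2),
    )


def extract_window(trace: OximetryTrace, window: AnalysisWindow) -> OximetryTrace:
    """Return the sub-trace whose timestamps fall in [window.start, window.end).

    The trace must span the window; timestamps are re-zeroed to the window
    start and ``start_clock`` is updated accordingly.
    """
    ws = (_clock_to_s(window.start) - _clock_to_s(trace.start_clock)) % (24 * 3600.0)
    we = ws + window.duration_s
    eps = 1e-9
    t = trace.elapsed_s
    if t.size == 0 or t[0] > ws + eps or t[-1] < we - 1.0 / trace.sample_rate - eps:
        span = f"[{t[0]:.1f}, {t[-1]:.1f}] s" if t.size else "(empty)"
        raise CoverageError(
            f"trace {trace.participant_id!r} spans {span} after "
            f"{trace.start_clock}, but window "
            f"{window.start}-{window.end} needs [{ws:.1f}, {we:.1f}) s"
        )
    sel = (t >= ws - eps) & (t < we - eps)
    return OximetryTrace(
        participant_id=trace.participant_id,
        start_clock=window.start,
        sample_rate=trace.sample_rate,
        elapsed_s=t[sel] - ws,
        spo2=trace.spo2[sel],
        hr=trace.hr[sel],
        valid=trace.valid[sel],
    )


def remove_artifacts(
    trace: OximetryTrace,
    *,
    max_value: float = SPO2_MAX,
    min_value: float = SPO2_MIN,
    max_step: float = MAX_STEP,
) -> OximetryTrace:
    """Mask measurement artifacts in the SpO2 channel.

    Samples with SpO2 strictly above ``max_value`` or strictly below
    ``min_value`` are invalidated first; then a single left-to-right scan
    invalidates any valid sample differing by strictly more than ``max_step``
    percentage points from the last surviving valid sample (isolated spikes
    are discarded, genuine plateaus retained). Idempotent; masked samples are
    never interpolated.
    """
    if trace.n_samples == 0:
        raise DegenerateTraceError(f"trace {trace.participant_id!r} is empty")
    in_range = trace.valid & (trace.spo2 <= max_value) & (trace.spo2 >= min_value)
    new_valid = _kernels.jump_scan(
        np.ascontiguousarray(trace.spo2, dtype=np.float64),
        np.ascontiguousarray(in_range, dtype=np.bool_),
        float(max_step),
    )
    if not new_valid.any():
        raise DegenerateTraceError(
            f"trace {trace.participant_id!r}: all samples removed as artifacts"
        )
    return replace(trace, valid=new_valid)


def hr_valid_mask(trace: OximetryTrace, lo: float = HR_MIN, hi: float = HR_MAX) -> np.ndarray:
    """Heart-rate validity: the SpO2 mask plus HR plausibility bounds."""
    return trace.valid & np.isfinite(trace.hr) & (trace.hr >= lo) & (trace.hr <= hi)
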