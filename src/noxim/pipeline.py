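"""End-to-end orchestration: simulate -> preprocess -> metrics -> events -> stats.

A run consumes a directory holding one delimited trace file per participant
plus a ``participants.csv`` metadata table (the layout ``write_cohort``
emits), applies window extraction and artifact removal, computes per-night
metrics and event ledgers, and writes the group-comparison and ROC prediction
reports together with a reproducibility manifest (seed, version, config
hash). Participants whose trace fails coverage or degenerates after filtering
(valid fraction below a configurable floor, default 0.5) are excluded with a
logged reason; the run fails only if more than a configurable fraction of
participants are unusable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .desat import DetectionParams, detect_events, events_to_table
from .errors import CoverageError, DegenerateTraceError, NoximError, ValidationError
from .metrics import FIELDS, compute_night_metrics
from .stats import (
    ParticipantRecord,
    group_comparison_table,
    prediction_table,
)
from .trace import (
    AnalysisWindow,
    TraceDialect,
    extract_window,
    parse_clock,
    read_trace,
    remove_artifacts,
)

log = logging.getLogger("noxim")

LLS_ITEMS = ("headache", "gi", "fatigue", "dizziness")


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of an analysis run; defaults echo the standard protocol."""

    window_start: str = "23:00"
    window_end: str = "05:00"
    artifact_max_value: float = 100.0
    artifact_min_value: float = 30.0
    artifact_max_step: float = 4.0
    desat_min_rate: float = 0.1
    desat_min_depth: float = 2.0
    desat_resat_baseline_margin: float = 1.0
    desat_resat_nadir_rise: float = 3.0
    desat_min_dur: float = 10.0
    desat_max_dur: float = 60.0
    desat_baseline_lookback_s: float = 30.0
    min_valid_fraction: float = 0.5
    max_excluded_fraction: float = 0.5
    bootstrap_replicates: int = 10_000
    seed: int = 0
    delimiter: str = ","
    time_col: str = "elapsed_s"
    spo2_col: str = "spo2_pct"
    hr_col: str = "hr_bpm"

    @property
    def window(self) -> AnalysisWindow:
        return AnalysisWindow(parse_clock(self.window_start), parse_clock(self.window_end))

    @property
    def detection(self) -> DetectionParams:
        return DetectionParams(
            min_rate=self.desat_min_rate,
            min_depth=self.desat_min_depth,
            resat_baseline_margin=self.desat_resat_baseline_margin,
            resat_nadir_rise=self.desat_resat_nadir_rise,
            min_dur=self.desat_min_dur,
            max_dur=self.desat_max_dur,
            baseline_lookback_s=self.desat_baseline_lookback_s,
        )

    @property
    def dialect(self) -> TraceDialect:
        return TraceDialect(self.delimiter, self.time_col, self.spo2_col, self.hr_col)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _lls(row: pd.Series, tag: str) -> tuple[int, int, int, int]:
    return tuple(int(row[f"lls_{tag}_{k}"]) for k in LLS_ITEMS)  # type: ignore[return-value]


def process_participant(
    trace_path: Path, config: RunConfig, participant_id: str
) -> tuple:
    """Window, filter and measure one trace; returns (metrics, events, fs)."""
    trace = read_trace(
        trace_path, config.dialect, participant_id=participant_id
    )
    windowed = extract_window(trace, config.window)
    clean = remove_artifacts(
        windowed,
        max_value=config.artifact_max_value,
        min_value=config.artifact_min_value,
        max_step=config.artifact_max_step,
    )
    if clean.valid_fraction < config.min_valid_fraction:
        raise DegenerateTraceError(
            f"{participant_id}: only {clean.valid_fraction:.0%} of the window "
            f"survived artifact removal (< {config.min_valid_fraction:.0%})"
        )
    events = detect_events(clean, config.detection)
    metrics = compute_night_metrics(clean, config.window, config.detection)
    return metrics, events, clean.sample_rate


@dataclass
class RunResult:
    records: list
    metrics_table: pd.DataFrame
    comparisons: pd.DataFrame
    predictions: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)


def analyze_directory(
    input_dir: str | Path, out_dir: str | Path, config: RunConfig = RunConfig()
) -> RunResult:
    """Run the full analysis over a cohort directory and persist all reports."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    meta_path = input_dir / "participants.csv"
    if not meta_path.exists():
        raise ValidationError(f"no participants.csv in {input_dir}")
    meta = pd.read_csv(meta_path)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "events").mkdir(exist_ok=True)

    records, metric_rows, excluded = [], [], {}
    for _, row in meta.iterrows():
        pid = str(row["participant_id"])
        try:
            metrics, events, fs = process_participant(
                input_dir / row["trace_file"], config, pid
            )
        except (CoverageError, DegenerateTraceError, NoximError) as exc:
            log.warning("excluding %s: %s", pid, exc)
            excluded[pid] = str(exc)
            continue
        events_to_table(events, fs).to_csv(out_dir / f"events/{pid}.csv", index=False)
        gsqs_cols = [c for c in meta.columns if c.startswith("gsqs_")]
        records.append(
            ParticipantRecord(
                participant_id=pid,
                group=str(row["group"]),
                lls_evening=_lls(row, "evening"),
                lls_morning=_lls(row, "morning"),
                gsqs_responses=tuple(bool(row[c]) for c in sorted(gsqs_cols)),
                metrics=metrics,
            )
        )
        metric_rows.append(
            {"participant_id": pid, "group": row["group"], **metrics.as_dict()}
        )

    if len(excluded) > config.max_excluded_fraction * len(meta):
        raise ValidationError(
            f"{len(excluded)}/{len(meta)} participants unusable: {excluded}"
        )
    if not records:
        raise ValidationError(f"no usable participants in {input_dir}")

    metrics_table = pd.DataFrame(metric_rows, columns=["participant_id", "group"] + FIELDS)
    comparisons = group_comparison_table(records)
    predictions = prediction_table(
        records, n_boot=config.bootstrap_replicates, seed=config.seed
    )

    metrics_table.to_csv(out_dir / "metrics.csv", index=False)
    comparisons.to_csv(out_dir / "group_comparisons.csv", index=False)
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    _write_manifest(out_dir, config, excluded)
    return RunResult(records, metrics_table, comparisons, predictions, excluded)


def _write_manifest(out_dir: Path, config: RunConfig, excluded: dict) -> None:
    cfg_text = config.to_yaml()
    (out_dir / "config.yaml").write_text(cfg_text)
    manifest = {
        "noxim_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_excluded": len(excluded),
        "excluded": excluded,
    }
    (out_dir / "manifest.txt").write_text(
        "\n".join(f"{k}: {json.dumps(v)}" for k, v in manifest.items()) + "\n"
    )


def report_from_tables(
    metrics_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Stats-only rerun from persisted metrics + metadata tables (no traces)."""
    from .metrics import NightMetrics

    metrics = pd.read_csv(metrics_path)
    meta = pd.read_csv(metadata_path).set_index("participant_id")
    records = []
    for _, row in metrics.iterrows():
        pid = str(row["participant_id"])
        mrow = meta.loc[pid]
        gsqs_cols = sorted(c for c in meta.columns if c.startswith("gsqs_"))
        records.append(
            ParticipantRecord(
                participant_id=pid,
                group=str(row["group"]),
                lls_evening=_lls(mrow, "evening"),
                lls_morning=_lls(mrow, "morning"),
                gsqs_responses=tuple(bool(mrow[c]) for c in gsqs_cols),
                metrics=NightMetrics(**{f: row[f] for f in FIELDS}),
            )
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comparisons = group_comparison_table(records)
    predictions = prediction_table(
        records, n_boot=config.bootstrap_replicates, seed=config.seed
    )
    comparisons.to_csv(out_dir / "group_comparisons.csv", index=False)
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    _write_manifest(out_dir, config, {})
    return RunResult(records, metrics, comparisons, predictions)
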