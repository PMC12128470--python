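"""Synthetic nocturnal-oximetry cohorts with ground-truth event ledgers.

The generator emulates a two-group altitude-simulation study: healthy adults
born pre-term vs term-born controls, each spending one night (22:00-06:00)
under severe normobaric hypoxia with fingertip SpO2 and heart rate sampled at
3 Hz. Each participant's SpO2 trace is a flat level plus a linear half-night
drift plus piecewise-linear desaturation excursions placed by a (per-
participant) Poisson process with non-overlap rejection, then quantized to
the 1% resolution of consumer pulse oximeters and corrupted with bursty
sensor artifacts (out-of-range spikes and large inter-sample jumps). A
morning acute-mountain-sickness outcome is drawn from a logistic link on the
realized window-mean SpO2, so generator-side realization noise propagates
into the outcome exactly as measured saturation would.

Two calibration choices keep the generator's parameters recoverable by the
analysis pipeline rather than merely nominal:

* ``mean_spo2`` is the target *realized* 6-h window mean: the flat level is
  offset by the exact per-trace excursion area, since desaturations would
  otherwise depress the realized mean by roughly burden/60 (~0.5% at
  pre-term defaults).
* event durations are *detector-referenced*: the excursion's plateau is
  solved per event so that the expected detected duration - applying the
  detection onset/termination rules analytically to the quantized,
  grid-sampled excursion - equals the drawn duration. Uncompensated,
  quantization and the sampling grid shorten detected durations by ~1.4 s,
  an order of magnitude more than the Monte-Carlo SE of a cohort mean.

Default parameter values reproduce the study's printed group summaries
(window mean 77%, ODI 69 vs 21 events/h, mean durations 17 vs 21 s, half-
night recovery -0.12 vs +1.11 points, heart rate 79 vs 71 beats/min, evening
AMS+ fractions 7/12 vs 9/12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trace import AnalysisWindow, OximetryTrace, TraceDialect, _clock_to_s


@dataclass(frozen=True)
class GroupParams:
    """Per-group generative parameters (units in comments)."""

    mean_spo2: float  # target realized 6-h window mean, %
    mean_spo2_sd: float  # between-participant SD, %
    drift: float  # half-night recovery: 2nd-half minus 1st-half mean, points
    drift_sd: float
    event_rate: float  # desaturation events per hour
    event_rate_cv: float  # between-participant CV of the rate
    duration_mean: float  # per-participant mean event duration, s
    duration_between_sd: float  # between-participant SD of that mean, s
    duration_within_sd: float  # within-participant per-event SD, s
    hr_mean: float  # beats/min
    hr_sd: float  # between-participant SD
    ams_intercept: float  # log-odds of morning AMS+ at the group-mean SpO2
    ams_slope: float  # log-odds per % SpO2 (negative: lower SpO2 -> AMS+)
    evening_ams_fraction: float
    gsqs_mean: float  # subjective sleep-quality composite, 0-14
    gsqs_sd: float


PRETERM_DEFAULTS = GroupParams(
    mean_spo2=77.0,
    mean_spo2_sd=3.0,
    drift=-0.12,
    drift_sd=1.51,
    event_rate=69.0,
    event_rate_cv=0.4,
    duration_mean=17.0,
    duration_between_sd=2.0,
    duration_within_sd=3.0,
    hr_mean=79.0,
    hr_sd=12.0,
    ams_intercept=0.0,  # ~6/12 AMS+ at the group mean
    ams_slope=-0.8,  # SpO2-coupled outcome: pre-term stratum effect size
    evening_ams_fraction=7.0 / 12.0,
    gsqs_mean=10.0,
    gsqs_sd=3.0,
)

TERM_DEFAULTS = GroupParams(
    mean_spo2=77.0,
    mean_spo2_sd=4.0,
    drift=1.11,
    drift_sd=0.78,
    event_rate=21.0,
    event_rate_cv=0.4,
    duration_mean=21.0,
    duration_between_sd=2.0,
    duration_within_sd=3.0,
    hr_mean=71.0,
    hr_sd=7.0,
    ams_intercept=math.log((5 / 12) / (7 / 12)),  # ~5/12 AMS+
    ams_slope=0.0,  # outcome decoupled from SpO2, as observed in controls
    evening_ams_fraction=9.0 / 12.0,
    gsqs_mean=9.0,
    gsqs_sd=5.0,
)

GROUPS = ("term-born", "pre-term")

TRACE_DIALECT = TraceDialect()  # columns elapsed_s, spo2_pct, hr_bpm


@dataclass(frozen=True)
class CohortSpec:
    """Study-level design: sizes, sampling, window, artifacts, group params."""

    n_per_group: int = 12
    sample_rate: float = 3.0
    night_hours: float = 8.0
    start_clock: time = time(22, 0)
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    artifact_rate: float = 0.001  # fraction of samples corrupted
    artifact_spike_fraction: float = 0.7  # rest are in-range jump bursts
    artifact_burst_mean: float = 4.0  # geometric mean burst length, samples
    depth_log_mu: float = 0.55  # depth = 2 + lognormal(mu, sigma): mean ~ 4 points
    depth_log_sigma: float = 0.5
    min_event_gap_s: float = 5.0
    preterm: GroupParams = PRETERM_DEFAULTS
    term: GroupParams = TERM_DEFAULTS
    seed: int = 0

    def validate(self) -> None:
        for g in (self.preterm, self.term):
            if g.event_rate < 0 or g.event_rate_cv < 0:
                raise ValidationError("event rates must be non-negative")
            if not 0 <= g.evening_ams_fraction <= 1:
                raise ValidationError("evening_ams_fraction must be in [0, 1]")
            if not 10 <= g.duration_mean <= 60:
                raise ValidationError("duration_mean must lie in [10, 60] s")
            # mean occupancy check: each event needs its duration plus ramp
            # tail and inter-event gap (~10 s overhead at default shapes)
            load = g.event_rate * self.night_hours * (
                g.duration_mean + self.min_event_gap_s + 10.0
            )
            if load > 0.85 * self.night_hours * 3600.0:
                raise ValidationError(
                    f"infeasible spec: mean event load {load:.0f} s exceeds "
                    f"the night ({self.night_hours * 3600:.0f} s)"
                )
            if g.mean_spo2_sd < 0 or g.drift_sd < 0 or g.hr_sd < 0:
                raise ValidationError("spread parameters must be non-negative")
        if self.n_per_group < 1 or self.sample_rate <= 0 or self.night_hours <= 0:
            raise ValidationError("invalid cohort dimensions")
        if not 0 <= self.artifact_rate < 0.5:
            raise ValidationError("artifact_rate must be a small fraction")

    def group_params(self, group: str) -> GroupParams:
        if group == "pre-term":
            return self.preterm
        if group == "term-born":
            return self.term
        raise ValidationError(f"unknown group {group!r}")


def _sample_truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


@dataclass
class _EventDesign:
    """Per-trace event draws in the physical (pre-quantization) frame."""

    phys_start: np.ndarray  # excursion departure time from night start, s
    duration: np.ndarray  # target detected duration, s
    depth: np.ndarray  # points
    r_down: np.ndarray  # descent rate, %/s
    r_up: np.ndarray  # recovery rate, %/s
    t_down: np.ndarray = None  # solved ramp times, s
    t_plateau: np.ndarray = None
    t_up_full: np.ndarray = None
    e_term: np.ndarray = None  # excursion depth at which the detector ends the event


def _draw_events(rng, gp: GroupParams, spec: CohortSpec, rate_h: float, dur_mu: float):
    """Draw event count, durations, depths, ramp rates; place without overlap."""
    T = spec.night_hours * 3600.0
    n = rng.poisson(rate_h * spec.night_hours)
    if n == 0:
        z = np.zeros(0)
        return _EventDesign(z, z.copy(), z.copy(), z.copy(), z.copy())

    # symmetric truncation keeps the per-participant mean duration unbiased
    dur_c = float(np.clip(dur_mu, 12.0, 56.0))
    half = min(5.5, dur_c - 10.5, 58.0 - dur_c)
    D = _sample_truncnorm(
        rng, dur_c, gp.duration_within_sd, dur_c - half, dur_c + half, n
    )
    depth = 2.0 + rng.lognormal(spec.depth_log_mu, spec.depth_log_sigma, size=n)
    depth = np.minimum(depth, np.minimum(10.0, 0.4 * D))
    r_down = rng.uniform(0.45, 0.9, size=n)
    r_up = rng.uniform(0.5, 1.0, size=n)

    g = spec.min_event_gap_s
    budget = D + 1.0 / r_down + depth / r_up + 1.0 / spec.sample_rate
    slack = T - budget.sum() - (n + 1) * g
    if slack < 0:
        raise ValidationError(
            f"infeasible event load: {n} events need "
            f"{budget.sum() + (n + 1) * g:.0f} s but the night has {T:.0f} s"
        )
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    starts = g + gaps[0] + np.concatenate(
        ([0.0], np.cumsum(budget[:-1] + g + gaps[1:-1]))
    )
    return _EventDesign(starts, D, depth, r_down, r_up)


def _solve_ramps(ev: _EventDesign, level, slope, t_mid, fs, t_p_min):
    """Solve each event's ramp times so the detector sees its drawn duration.

    Works against the integer quantization grid: with local continuous level
    c and B = round(c), the quantized trace first drops below B once the
    excursion e exceeds delta = c - (B - 0.5), and the detector's termination
    rules (>= B-1, or >= quantized nadir + 3) fire once e recedes to
    e_term = max(delta + 1, c - round(c - depth) - 2.5). Expected half-sample
    offsets at onset and end contribute +1/fs, which the plateau absorbs.
    """
    n = ev.phys_start.size
    ev.t_down = np.zeros(n)
    ev.t_plateau = np.zeros(n)
    ev.t_up_full = np.zeros(n)
    ev.e_term = np.zeros(n)
    for i in range(n):
        c = level + slope * (ev.phys_start[i] - t_mid)
        B = np.round(c)
        delta = c - (B - 0.5)
        N = np.round(c - ev.depth[i])
        e_term = max(delta + 1.0, c - N - 2.5)
        need = ev.duration[i] - 1.0 / fs - t_p_min
        rd = max(ev.r_down[i], (ev.depth[i] - delta) / (0.7 * need))
        ru = max(ev.r_up[i], (ev.depth[i] - e_term) / (0.3 * need))
        ev.t_down[i] = ev.depth[i] / rd
        ev.t_up_full[i] = ev.depth[i] / ru
        ev.t_plateau[i] = (
            ev.duration[i]
            - 1.0 / fs
            - (ev.depth[i] - delta) / rd
            - (ev.depth[i] - e_term) / ru
        )
        ev.e_term[i] = e_term
        ev.r_down[i] = rd
        ev.r_up[i] = ru


def _excursion_array(ev: _EventDesign, t: np.ndarray) -> np.ndarray:
    """Sum of piecewise-linear excursion depths sampled at times ``t``."""
    e = np.zeros_like(t)
    fs_span = t[1] - t[0] if t.size > 1 else 1.0
    for i in range(ev.phys_start.size):
        t0 = ev.phys_start[i]
        t1 = t0 + ev.t_down[i]
        t2 = t1 + ev.t_plateau[i]
        t3 = t2 + ev.t_up_full[i]
        lo = max(0, int(t0 / fs_span))
        hi = min(t.size, int(t3 / fs_span) + 2)
        ts = t[lo:hi]
        seg = np.zeros_like(ts)
        m = (ts >= t0) & (ts < t1)
        seg[m] = (ts[m] - t0) * ev.depth[i] / ev.t_down[i]
        m = (ts >= t1) & (ts < t2)
        seg[m] = ev.depth[i]
        m = (ts >= t2) & (ts < t3)
        seg[m] = np.maximum(
            0.0, ev.depth[i] - (ts[m] - t2) * ev.depth[i] / ev.t_up_full[i]
        )
        e[lo:hi] += seg
    return e


def _ledger(ev: _EventDesign, level, slope, t_mid, fs) -> pd.DataFrame:
    """Ground-truth event table in the detector's reference frame."""
    rows = []
    for i in range(ev.phys_start.size):
        c = level + slope * (ev.phys_start[i] - t_mid)
        B = float(np.round(c))
        delta = c - (B - 0.5)
        rd = ev.depth[i] / ev.t_down[i]
        ru = ev.depth[i] / ev.t_up_full[i]
        onset = ev.phys_start[i] + delta / rd - 0.5 / fs
        end = onset + ev.duration[i]
        nadir = ev.phys_start[i] + ev.t_down[i]
        a_down = 0.5 * ev.depth[i] * ev.t_down[i]
        a_flat = ev.depth[i] * ev.t_plateau[i]
        a_up = 0.5 * (ev.depth[i] + ev.e_term[i]) * (ev.depth[i] - ev.e_term[i]) / ru
        rows.append(
            {
                "onset_s": onset,
                "nadir_s": nadir,
                "end_s": end,
                "baseline": B,
                "depth": float(ev.depth[i]),
                "duration_s": float(ev.duration[i]),
                "area": (a_down + a_flat + a_up) / 60.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["onset_s", "nadir_s", "end_s", "baseline", "depth", "duration_s", "area"],
    )


def _inject_artifacts(rng, spo2, hr, spec: CohortSpec):
    """Bursty sensor corruption: out-of-range spikes and in-range jumps."""
    n = spo2.size
    target = spec.artifact_rate * n
    n_bursts = rng.poisson(target / spec.artifact_burst_mean)
    for _ in range(n_bursts):
        length = rng.geometric(1.0 / spec.artifact_burst_mean)
        s = rng.integers(0, max(1, n - length))
        sl = slice(s, min(n, s + length))
        if rng.random() < spec.artifact_spike_fraction:
            if rng.random() < 0.5:
                spo2[sl] = rng.uniform(100.5, 127.0, size=sl.stop - sl.start)
            else:
                spo2[sl] = rng.uniform(2.0, 29.5, size=sl.stop - sl.start)
        else:
            off = rng.uniform(5.0, 25.0) * (1 if rng.random() < 0.5 else -1)
            spo2[sl] = np.clip(spo2[sl] + off, 30.0, 100.0)
        hr[sl] = rng.choice([0.0, 300.0])
    return spo2, hr


def generate_trace(
    spec: CohortSpec, group: str, rng: np.random.Generator | int | None = None
) -> tuple[OximetryTrace, pd.DataFrame, dict]:
    """One participant's night: (trace, ground-truth ledger, truth dict).

    The ledger records every designed event (onset_s, nadir_s, end_s,
    baseline, depth, duration_s, area) in the detector's reference frame; by
    construction each satisfies the rate / magnitude / re-saturation /
    duration criteria on the quantized trace, absent artifact interference.
    """
    spec.validate()
    gp = spec.group_params(group)
    rng = np.random.default_rng(rng)
    fs = spec.sample_rate
    n = int(round(spec.night_hours * 3600 * fs))
    t = np.arange(n) / fs

    mu = rng.normal(gp.mean_spo2, gp.mean_spo2_sd)
    drift = rng.normal(gp.drift, gp.drift_sd)
    dur_mu = float(rng.normal(gp.duration_mean, gp.duration_between_sd))
    hr_mu = float(rng.normal(gp.hr_mean, gp.hr_sd))

    ws = (_clock_to_s(spec.window.start) - _clock_to_s(spec.start_clock)) % 86400.0
    wd = spec.window.duration_s
    t_mid = ws + wd / 2.0
    slope = drift / (wd / 2.0)  # half-night mean difference -> points per second
    in_window = (t >= ws) & (t < ws + wd)

    # per-participant rate, occupancy-truncated: draws whose event load cannot
    # fit the night (a physical bound) are rejected and redrawn
    for _ in range(1000):
        if gp.event_rate_cv > 0 and gp.event_rate > 0:
            k = 1.0 / gp.event_rate_cv**2
            rate_h = float(rng.gamma(k, gp.event_rate / k))
        else:
            rate_h = gp.event_rate
        try:
            ev = _draw_events(rng, gp, spec, rate_h, dur_mu)
            break
        except ValidationError:
            continue
    else:
        raise ValidationError("could not place events: spec load too close to capacity")
    t_p_min = 2.0 / fs

    # pass 1: provisional level, to measure the excursion's window-mean cost
    _solve_ramps(ev, mu, slope, t_mid, fs, t_p_min)
    offset = _excursion_array(ev, t)[in_window].mean() if ev.phys_start.size else 0.0
    # pass 2: final level compensates that cost, so realized window mean == mu
    level = mu + offset
    _solve_ramps(ev, level, slope, t_mid, fs, t_p_min)
    excursion = _excursion_array(ev, t)
    level = mu + excursion[in_window].mean()

    continuous = level + slope * (t - t_mid) - excursion
    spo2 = np.round(continuous)  # 1% oximeter quantization
    hr = np.round(rng.normal(hr_mu, 3.0, size=n))

    realized_mean = float(spo2[in_window].mean())
    spo2, hr = _inject_artifacts(rng, spo2, hr, spec)

    ledger = _ledger(ev, level, slope, t_mid, fs)
    truth = {
        "group": group,
        "mean_spo2": mu,
        "drift": drift,
        "event_rate": rate_h,
        "duration_mean": dur_mu,
        "hr_mean": hr_mu,
        "n_events": int(ev.phys_start.size),
        "realized_mean_spo2": realized_mean,
    }
    trace = OximetryTrace(
        participant_id="",
        start_clock=spec.start_clock,
        sample_rate=fs,
        elapsed_s=t,
        spo2=spo2,
        hr=hr,
        valid=np.ones(n, dtype=bool),
    )
    return trace, ledger, truth


# --- questionnaires ----------------------------------------------------------


def _sample_lls_items(rng, positive: bool) -> tuple[int, int, int, int]:
    """Four symptom scores consistent with the requested AMS classification."""
    if positive:
        headache = int(rng.integers(1, 3))
        others = rng.integers(0, 2, size=3)
        while headache + others.sum() < 3:
            j = int(rng.integers(0, 3))
            if others[j] < 3:
                others[j] += 1
        return (headache, int(others[0]), int(others[1]), int(others[2]))
    if rng.random() < 0.5:
        return (0, 0, 0, 0)
    if rng.random() < 0.5:  # headache but sub-threshold total
        return (1, int(rng.integers(0, 2)), 0, 0)
    return (0, int(rng.integers(0, 3)), int(rng.integers(0, 3)), 0)  # no headache


def _sample_gsqs_responses(rng, gp: GroupParams) -> tuple[bool, ...]:
    """15 true/false statements whose keyed composite hits a drawn target."""
    target = int(np.clip(np.round(rng.normal(gp.gsqs_mean, gp.gsqs_sd)), 0, 14))
    scored = rng.permutation(14)[:target]  # items 2..15 carry the 14 key points
    resp = np.zeros(15, dtype=bool)
    resp[1 + scored] = True
    resp[0] = rng.random() < 0.5  # unscored warm-up item
    return tuple(bool(x) for x in resp)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class SimulatedParticipant:
    participant_id: str
    group: str
    trace: OximetryTrace
    ledger: pd.DataFrame
    truth: dict
    lls_evening: tuple[int, int, int, int]
    lls_morning: tuple[int, int, int, int]
    gsqs_responses: tuple[bool, ...]


def generate_cohort(
    spec: CohortSpec = CohortSpec(), seed: int | None = None
) -> list[SimulatedParticipant]:
    """Generate the full two-group cohort (traces, ledgers, questionnaires).

    Morning AMS+ is drawn from the logistic link on the realized window-mean
    SpO2; evening AMS+ is drawn at the configured marginal fraction and the
    Lake Louise items are sampled consistently with each flag. Deterministic
    for a given (spec, seed).
    """
    spec.validate()
    root = np.random.default_rng(spec.seed if seed is None else seed)
    out = []
    for group in GROUPS:
        gp = spec.group_params(group)
        tag = "T" if group == "term-born" else "P"
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            trace, ledger, truth = generate_trace(spec, group, rng)
            pid = f"{tag}{i + 1:02d}"
            trace.participant_id = pid
            p_morning = _sigmoid(
                gp.ams_intercept
                + gp.ams_slope * (truth["realized_mean_spo2"] - gp.mean_spo2)
            )
            morning = bool(rng.random() < p_morning)
            evening = bool(rng.random() < gp.evening_ams_fraction)
            out.append(
                SimulatedParticipant(
                    participant_id=pid,
                    group=group,
                    trace=trace,
                    ledger=ledger,
                    truth=truth,
                    lls_evening=_sample_lls_items(rng, evening),
                    lls_morning=_sample_lls_items(rng, morning),
                    gsqs_responses=_sample_gsqs_responses(rng, gp),
                )
            )
    return out


def write_cohort(
    participants: list[SimulatedParticipant], out_dir: str | Path
) -> Path:
    """Write per-participant trace files, ledgers and the metadata table.

    Emits the same delimited dialect the pipeline consumes; returns the
    metadata table path.
    """
    out_dir = Path(out_dir)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    (out_dir / "ledgers").mkdir(parents=True, exist_ok=True)
    rows = []
    for p in participants:
        fname = f"traces/{p.participant_id}.csv"
        df = pd.DataFrame(
            {
                "elapsed_s": np.round(p.trace.elapsed_s, 4),
                "spo2_pct": p.trace.spo2,
                "hr_bpm": p.trace.hr,
            }
        )
        df.to_csv(out_dir / fname, index=False)
        p.ledger.to_csv(out_dir / f"ledgers/{p.participant_id}.csv", index=False)
        row = {
            "participant_id": p.participant_id,
            "group": p.group,
            "trace_file": fname,
        }
        for tag, items in (("evening", p.lls_evening), ("morning", p.lls_morning)):
            for name, v in zip(("headache", "gi", "fatigue", "dizziness"), items):
                row[f"lls_{tag}_{name}"] = v
        for j, r in enumerate(p.gsqs_responses, start=1):
            row[f"gsqs_{j:02d}"] = int(r)
        rows.append(row)
    meta = pd.DataFrame(rows)
    meta_path = out_dir / "participants.csv"
    meta.to_csv(meta_path, index=False)
    return meta_path
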