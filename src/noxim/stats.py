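"""Questionnaire scoring, group comparisons and ROC-based AMS prediction.

Acute mountain sickness (AMS) is scored with the Lake Louise scale: four
self-reported symptoms (headache, gastrointestinal distress, fatigue/weakness,
dizziness) each 0-3; a participant is AMS+ when the total is at least 3 with a
headache score of at least 1. Subjective sleep quality uses the Groningen
Sleep Quality Scale: 15 true/false statements, keyed composite 0-14, higher =
worse sleep.

Between-group comparisons are routed by a Shapiro-Wilk normality check on
both groups (alpha 0.05): Student's independent t-test with mean +/- SD
summaries when both pass, Mann-Whitney U with median[IQR] otherwise.

Predictive potential of each nocturnal variable for morning AMS is quantified
by the ROC area under the curve (rank statistic, ties counted 1/2), a 95%
percentile interval from a stratified bootstrap (cases and controls resampled
independently with replacement; 10,000 replicates by default), and - when the
CI lower bound exceeds 0.5, i.e. better than a random classifier - the
Youden-optimal threshold with its sensitivity and specificity. Orientation is
fixed a priori per variable from physiological direction (AUC may fall below
0.5): lower saturation-level metrics predict AMS+, higher event/HR/TST80
metrics predict AMS+.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .metrics import NightMetrics

#: orientation per predictor: does a *lower* or *higher* value flag AMS+?
ORIENTATION = {
    "mean_spo2": "lower",
    "min_spo2": "lower",
    "morning_spo2": "lower",
    "delta_spo2": "lower",
    "tst80": "higher",
    "mean_hr": "higher",
    "n_desat": "higher",
    "odi": "higher",
    "mean_desat_duration": "higher",
    "hypoxic_burden": "higher",
}

PREDICTORS = list(ORIENTATION)

#: Package default scoring key for the 15-item sleep questionnaire: the first
#: item is an unscored warm-up, items 2-15 each contribute one point when
#: endorsed (composite 0-14). The instrument's published key is not
#: redistributable here; override via the ``key`` argument if you hold it.
DEFAULT_GSQS_KEY = (0,) + (1,) * 14


def classify_ams(lls_items: Sequence[int]) -> bool:
    """AMS+ rule: total symptom score >= 3 with headache (first item) >= 1."""
    items = list(lls_items)
    if len(items) != 4:
        raise ValidationError(f"expected 4 symptom items, got {len(items)}")
    for v in items:
        if v not in (0, 1, 2, 3):
            raise ValidationError(f"symptom item {v!r} outside 0-3")
    return sum(items) >= 3 and items[0] >= 1


def score_gsqs(responses: Sequence[bool], key: Sequence[int] = DEFAULT_GSQS_KEY) -> int:
    """Keyed composite of the 15 sleep-quality statements, in [0, 14]."""
    if len(responses) != 15:
        raise ValidationError(f"expected 15 responses, got {len(responses)}")
    if len(key) != 15 or sum(key) != 14:
        raise ValidationError("scoring key must have 15 entries summing to 14")
    return int(sum(k for k, r in zip(key, responses) if r))


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # "t-test" or "mann-whitney"
    summary_a: tuple[float, float]  # (mean, sd) or (median, iqr)
    summary_b: tuple[float, float]
    p_value: float
    significant: bool


def _shapiro_ok(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # constant sample: normality undefined -> fail
        return False
    p = sps.shapiro(x).pvalue
    return bool(np.isfinite(p) and p >= alpha)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    variable: str = "",
) -> GroupComparison:
    """Normality-routed two-group comparison (see module docstring)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs at least 3 observations")
    if _shapiro_ok(a, alpha) and _shapiro_ok(b, alpha):
        p = float(sps.ttest_ind(a, b).pvalue)
        return GroupComparison(
            variable,
            "t-test",
            (float(a.mean()), float(a.std(ddof=1))),
            (float(b.mean()), float(b.std(ddof=1))),
            p,
            p < 0.05,
        )
    p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    def med_iqr(x):
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
        return (float(q2), float(q3 - q1))

    return GroupComparison(variable, "mann-whitney", med_iqr(a), med_iqr(b), p, p < 0.05)


def _oriented(values: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "higher":
        return values
    if orientation == "lower":
        return -values
    raise ValidationError(f"orientation must be 'lower' or 'higher', got {orientation!r}")


def _split(values, outcome):
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if x.shape != y.shape:
        raise ValidationError("predictor and outcome lengths differ")
    cases, controls = x[y], x[~y]
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("both outcome classes must be nonempty")
    return cases, controls


def roc_auc(
    values: Sequence[float], outcome: Sequence[bool], orientation: str = "higher"
) -> float:
    """Rank-statistic AUC with ties counted 1/2; orientation applied first."""
    cases, controls = _split(_oriented(np.asarray(values, float), orientation), outcome)
    ranks = sps.rankdata(np.concatenate([cases, controls]))
    n1, n0 = cases.size, controls.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _auc_rows(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """AUC per row for (B, n1) cases vs (B, n0) controls, pairwise with 1/2 ties."""
    diff = cases[:, :, None] - controls[:, None, :]
    return ((diff > 0).mean(axis=(1, 2)) + 0.5 * (diff == 0).mean(axis=(1, 2)))


def bootstrap_auc_ci(
    values: Sequence[float],
    outcome: Sequence[bool],
    orientation: str = "higher",
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile CI for the AUC from a stratified bootstrap.

    Cases and controls are resampled independently with replacement, which
    preserves both class sizes (no replicate can lose a class). Seeded and
    reproducible via ``rng``.
    """
    rng = np.random.default_rng(rng)
    cases, controls = _split(_oriented(np.asarray(values, float), orientation), outcome)
    bc = cases[rng.integers(0, cases.size, size=(n_boot, cases.size))]
    bn = controls[rng.integers(0, controls.size, size=(n_boot, controls.size))]
    aucs = _auc_rows(bc, bn)
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def youden_threshold(
    values: Sequence[float], outcome: Sequence[bool], orientation: str = "higher"
) -> tuple[float, float, float]:
    """Maximize J = sensitivity + specificity - 1 over all cutpoints.

    Candidates are midpoints between adjacent sorted unique oriented values
    plus +/- infinity; classification is "oriented value above cutpoint =>
    AMS+". Ties on J resolve toward higher sensitivity, then the lower
    raw-unit threshold. Returns (raw threshold, sensitivity, specificity).
    """
    x = np.asarray(values, dtype=float)
    s = _oriented(x, orientation)
    cases, controls = _split(s, outcome)
    uniq = np.unique(s)
    cand = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    sens = (cases[None, :] > cand[:, None]).mean(axis=1)
    spec = (controls[None, :] <= cand[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    raw = cand if orientation == "higher" else -cand
    best = None
    for i in range(cand.size):
        key = (round(j[i], 12), round(sens[i], 12), -raw[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return float(raw[i]), float(sens[i]), float(spec[i])


@dataclass(frozen=True)
class RocResult:
    predictor: str
    orientation: str
    auc: float
    ci_low: float
    ci_high: float
    better_than_random: bool
    youden_threshold: float  # nan unless better_than_random
    sensitivity: float
    specificity: float


def roc_analysis(
    values: Sequence[float],
    outcome: Sequence[bool],
    predictor: str,
    orientation: str | None = None,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> RocResult:
    """Full ROC workup for one predictor: AUC, bootstrap CI, Youden if flagged."""
    orientation = orientation or ORIENTATION.get(predictor, "higher")
    auc = roc_auc(values, outcome, orientation)
    lo, hi = bootstrap_auc_ci(values, outcome, orientation, n_boot=n_boot, rng=rng)
    flagged = lo > 0.5
    thr = sens = spec = float("nan")
    if flagged:
        thr, sens, spec = youden_threshold(values, outcome, orientation)
    return RocResult(predictor, orientation, auc, lo, hi, flagged, thr, sens, spec)


# --- cohort-level report builders -------------------------------------------


@dataclass(frozen=True)
class ParticipantRecord:
    """Group label, questionnaire scores, AMS flags and nocturnal metrics."""

    participant_id: str
    group: str  # "pre-term" or "term-born"
    lls_evening: tuple[int, int, int, int]
    lls_morning: tuple[int, int, int, int]
    gsqs_responses: tuple[bool, ...]
    metrics: NightMetrics

    @property
    def ams_evening(self) -> bool:
        return classify_ams(self.lls_evening)

    @property
    def ams_morning(self) -> bool:
        return classify_ams(self.lls_morning)

    @property
    def gsqs_score(self) -> int:
        return score_gsqs(self.gsqs_responses)


STRATA = ("all", "term-born", "pre-term")


def prediction_table(
    records: Sequence[ParticipantRecord],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """ROC report (AUC, CI, flag, Youden cells) per predictor and cohort stratum.

    A stratum whose morning AMS outcome is single-class cannot support ROC
    analysis; its rows carry NaNs and a note, other strata are unaffected.
    Desaturation count and ODI yield identical AUCs (one is a constant
    multiple of the other).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for stratum in STRATA:
        sub = [
            r
            for r in records
            if stratum == "all" or r.group == stratum
        ]
        outcome = np.array([r.ams_morning for r in sub], dtype=bool)
        for pred in PREDICTORS:
            child = np.random.default_rng(ss.spawn(1)[0])
            vals = np.array([getattr(r.metrics, pred) for r in sub], dtype=float)
            try:
                res = roc_analysis(vals, outcome, pred, n_boot=n_boot, rng=child)
                rows.append(
                    {
                        "stratum": stratum,
                        "predictor": pred,
                        "n": len(sub),
                        "n_pos": int(outcome.sum()),
                        "auc": res.auc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "better_than_random": res.better_than_random,
                        "youden_threshold": res.youden_threshold,
                        "sensitivity": res.sensitivity,
                        "specificity": res.specificity,
                        "note": "",
                    }
                )
            except ValidationError as exc:
                rows.append(
                    {
                        "stratum": stratum,
                        "predictor": pred,
                        "n": len(sub),
                        "n_pos": int(outcome.sum()) if len(sub) else 0,
                        "auc": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "better_than_random": False,
                        "youden_threshold": np.nan,
                        "sensitivity": np.nan,
                        "specificity": np.nan,
                        "note": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def group_comparison_table(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Normality-routed pre-term vs term-born comparison for every variable."""
    pre = [r for r in records if r.group == "pre-term"]
    term = [r for r in records if r.group == "term-born"]
    rows = []
    variables = PREDICTORS + ["gsqs"]
    for var in variables:
        if var == "gsqs":
            a = [float(r.gsqs_score) for r in pre]
            b = [float(r.gsqs_score) for r in term]
        else:
            a = [getattr(r.metrics, var) for r in pre]
            b = [getattr(r.metrics, var) for r in term]
        a = [v for v in a if np.isfinite(v)]
        b = [v for v in b if np.isfinite(v)]
        try:
            cmp = compare_groups(a, b, variable=var)
            rows.append(
                {
                    "variable": var,
                    "test_used": cmp.test_used,
                    "preterm_center": cmp.summary_a[0],
                    "preterm_spread": cmp.summary_a[1],
                    "term_center": cmp.summary_b[0],
                    "term_spread": cmp.summary_b[1],
                    "p_value": cmp.p_value,
                    "significant": cmp.significant,
                    "note": "",
                }
            )
        except ValidationError as exc:
            rows.append(
                {
                    "variable": var,
                    "test_used": "",
                    "preterm_center": np.nan,
                    "preterm_spread": np.nan,
                    "term_center": np.nan,
                    "term_spread": np.nan,
                    "p_value": np.nan,
                    "significant": False,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)
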