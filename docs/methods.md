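# Methods

This note documents the model choices behind `noxim`: what each stage
assumes, which knobs matter, what the synthetic cohorts do and do not
emulate, and the numerical decisions taken where the underlying definitions
were genuinely open.

## Trace model and artifact handling

A recording is a uniform 3 Hz grid of SpO2 (%) and heart rate (beats/min)
carrying explicit elapsed-time stamps, so files with gaps stay addressable
by clock time. Artifact handling is *masking only*: samples are flagged
invalid and excluded from every downstream statistic, but never dropped,
interpolated or smoothed — index positions and timestamps are preserved so
event times remain physical.

Two artifact rules apply to SpO2, with strict inequalities: absolute values
above 100% or below 30%, and inter-sample changes above 4 percentage points.
The jump rule does not say which member of an offending pair is spurious; we
use a single sequential left-to-right scan that invalidates the *current*
sample whenever it differs by more than 4 points from the last *surviving*
sample, and keeps comparing against that survivor. This is deterministic,
idempotent, removes isolated spikes of any length, and retains genuine
plateaus; its cost is that a true instantaneous step of more than 4 points
(physiologically implausible at 3 Hz) would mask the later level. Range
removal runs before the jump scan. Heart rate has no published artifact
rule; it inherits the SpO2 mask plus plausibility bounds (25–250 beats/min,
configurable).

The analysis window (default 23:00–05:00, i.e. the central 6 h of a
22:00–06:00 night) is half-open: a sample stamped exactly at the end is
excluded, so a gapless 3 Hz night contributes exactly 64,800 samples.

## Composite variables

All statistics are over valid samples. Two conventions needed fixing:

* **TST80 denominator** — the fraction of time below 80% is reported
  against *valid* time, so TST80 + time-at-or-above-80 = 100% by
  construction; `valid_fraction` is reported alongside, which makes the
  raw-duration alternative recoverable (multiply by it).
* **Halves for ΔSpO2** — the two halves of the night are defined by clock
  time (window midpoint), not by valid-sample count: "half of the night" is
  a temporal notion. Positive ΔSpO2 = overnight recovery.

Morning SpO2 is the mean over the final hour of the window, half-open.

## Desaturation events

The criteria — descent rate > 0.1 %/s, depth ≥ 2 points below baseline,
re-saturation at the first return to within 1 point of baseline or 3 points
above the nadir (whichever first), total duration 10–60 s inclusive — leave
several operational choices open. Ours:

* **Baseline**: the maximum of the preceding 30 s of valid signal (onset
  sample included), confined to the current contiguous valid segment.
  A short look-back tracks slow drift; 30 s is configurable.
* **Rate**: mean slope (baseline − nadir)/(t_nadir − t_onset), not an
  instantaneous slope, which is ill-conditioned on a 1%-quantized signal
  at 3 Hz.
* **Termination semantics**: after onset, the earliest running minimum is
  the nadir; the two re-saturation rules are tested only on samples
  *strictly above* the running minimum. Flat dwells at an intermediate
  level therefore never terminate an event — necessary on quantized
  signals, where the first descending step otherwise sits exactly at
  baseline − 1 and would end every event during its own descent.
* **Scan policy**: after an accepted event the scan resumes one sample past
  its end (a renewed decline inside an event is not a second event); after
  a failed candidate it advances one sample. A consequence is that a
  too-slow decline can still yield an event from a later sub-candidate
  whose mean slope clears the rate bound while the 30 s look-back still
  grants it full depth; this is a faithful reading of the criteria applied
  at every possible onset, and it vanishes for genuinely slow drift
  (≥ 2 points within ~30 s would be needed).
* **Gaps**: candidates never span masked samples; each valid segment is
  scanned independently. Masked samples carry no information and bridging
  would fabricate slopes.
* Nadir ties go to the earliest sample; events are non-overlapping and
  time-ordered by construction.

The per-event hypoxic area is the trapezoidal integral of
max(0, baseline − SpO2) from onset to termination, in %·min; ODI and burden
normalize by the *window* duration (6 h), matching the convention that the
event count and ODI differ by a constant factor.

The scanning kernel is numba-compiled for whole-night traces; the
pure-Python definition is the reference semantics (exercised in tests via
`py_func`) and is used as-is when numba is absent.

## Questionnaires and statistics

AMS+ requires a Lake Louise total ≥ 3 with headache ≥ 1 (items 0–3 each).
The 15-statement sleep-quality scale scores a 0–14 composite; the published
per-item key is not redistributable, so the package default scores items
2–15 one point each (item 1 an unscored warm-up) and is configurable — the
generator and scorer share whatever key is supplied.

Group comparisons route on Shapiro–Wilk at α = 0.05 applied to *both*
groups: t-test with mean ± SD when both pass, Mann–Whitney U with
median [IQR] otherwise. Constant samples (normality undefined) take the
nonparametric route.

ROC orientation is fixed a priori from physiological direction — lower
mean/min/morning SpO2 and ΔSpO2 predict AMS+, higher TST80, heart rate,
event count, ODI, duration and burden predict AMS+ — so observed AUCs may
fall below 0.5; no data-driven orientation is applied. The bootstrap CI is
the percentile interval of 10,000 stratified replicates (cases and controls
resampled independently, which preserves class sizes, so no replicate can
degenerate). Percentile is the simplest defensible flavour; BCa was left
out deliberately. Youden's J is maximized over midpoints of adjacent sorted
unique predictor values plus ±∞, classification being "oriented value above
cutpoint"; ties on J resolve toward higher sensitivity, then the lower raw
threshold, making thresholds reproducible raw-unit numbers.

## Synthetic cohorts

Each participant's SpO2 trace is: flat level + linear drift (centred on the
window midpoint, scaled so the half-night mean difference equals the drift
parameter) − a sum of piecewise-linear desaturation excursions, quantized
to 1% steps, then corrupted by bursty artifacts. Defaults reproduce the
study conditions the pipeline targets: 12 participants per group, window
mean 77% (SD 3 pre-term / 4 term-born), event rates 69 vs 21 per hour
(between-participant CV 0.4), per-participant mean durations 17 vs 21 s
(between SD 2, within SD 3), drift −0.12 vs +1.11 points, heart rates
79 ± 12 vs 71 ± 7, evening AMS+ fractions 7/12 vs 9/12, morning AMS+ drawn
from a logistic link on realized mean SpO2 (slope −0.8/% pre-term, 0
term-born — the coupling is a pre-term-only effect). Event depths are
2 + lognormal(0.55, 0.5) points (mean ≈ 4, capped at 0.4 × duration);
descent and recovery ramp rates are drawn uniformly well above the 0.1 %/s
bound.

Three calibration choices make the parameters *recoverable* rather than
nominal:

* the flat level is offset by the exact per-trace excursion area so the
  realized window mean equals the drawn `mean_spo2` (events would otherwise
  depress it by ≈ burden/60, ~0.5% at pre-term defaults);
* each excursion's plateau is solved against the integer quantization grid
  and the sampling grid so that the *detected* duration (applying the
  detector's onset and termination rules analytically) is centred on the
  drawn duration; uncompensated, the grid shortens detected durations by
  ≈ 1.4 s, an order of magnitude beyond the Monte-Carlo SE of a cohort
  mean;
* per-participant rates are occupancy-truncated: a draw whose events
  physically cannot fit the night (with a 5 s minimum gap) is redrawn, and
  a spec whose *mean* load exceeds the night is rejected outright.

Artifacts arrive in bursts (Poisson onsets, geometric lengths, mean 4
samples; 0.1% of samples corrupted overall) as a 70/30 mix of out-of-range
spikes and large in-range jumps, with heart rate corrupted in the same
bursts. Burstiness mirrors motion artifacts and determines how many events
are split by masking — at the default rate the detector keeps recall above
~95% with false discovery well under 1%.

What the generator does **not** emulate: beat-to-beat measurement noise
(the quantized staircase is otherwise clean, which is why false discoveries
are near zero — real traces will be noisier), periodic-breathing cycle
structure or any ventilatory mechanism, non-stationary event rates
(placement is homogeneous), within-night sleep/wake structure, and the
depth/area joint distribution of real desaturations — with mean depth ≈ 4
points the synthetic hypoxic burden (~50 %·min/h at pre-term defaults) runs
higher relative to its ODI than typical field data. TST80 is also lumpier
than real data: with only drift and events, a participant's night sits
mostly on one side of 80%. Passing recovery tests therefore demonstrates
pipeline correctness under the stated statistical structure, not
field-data realism.

## Problem sizes and tolerances

Detector–reference equivalence is asserted exactly on 1,000 random
quantized walks (≤ 500 samples, random masks). Parameter recovery uses 20
cohort replicates (480 nights) and asserts each detected group summary
within ±2 Monte-Carlo SE of its generating value. Bootstrap coverage uses
500 outer replicates at B = 2,000, n = 6 + 6, true AUC 0.8, asserting
≥ 85% (small-n percentile intervals under-cover slightly; 88% observed).
Null-model specificity uses 50 cohorts with the AMS link severed: per-cell
false-flag rates sit at or below the ~5% nominal level (≈ 4% observed), but
with ~30 partially dependent predictor × stratum cells per cohort the
*any-flag* rate is structurally large (≈ 46%); the suite keeps a failing
check documenting that a cohort-level multiplicity control would be needed
to bound it — none is applied, mirroring standard practice of reporting
per-predictor CIs without familywise correction.

## Known limitations

* Closed-form ledger areas describe the designed continuous excursion;
  detected areas differ by quantization (≲ 1% relative at defaults).
* The exclusion rule for unusable nights (valid fraction < 0.5 after
  masking, coverage failures) is explicit but necessarily a convention;
  real studies describe such exclusions qualitatively.
* ROC analyses are in-sample: no train/test split or cross-validated
  logistic model is attempted, and with n = 12 per stratum thresholds and
  sensitivities are coarse (multiples of 1/6).
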