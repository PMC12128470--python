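# noxim — nocturnal pulse-oximetry analysis for altitude studies

`noxim` turns raw overnight fingertip pulse-oximetry recordings (SpO2 and
heart rate, nominally 3 Hz) into the standard descriptors of nocturnal
hypoxaemia, and asks whether any of them predicts next-morning acute
mountain sickness (AMS). It was built for sleep-at-altitude studies — for
example a night in normobaric hypoxia at FiO2 ≈ 0.14 (≈ 4200 m equivalent)
comparing adults born very pre-term with term-born controls — but the
pipeline applies to any overnight SpO2 trace delivered as delimited text.

## What it computes

**Preprocessing.** The central analysis window (default 23:00–05:00,
half-open) is extracted and artifacts are masked, never interpolated:
SpO2 > 100% or < 30%, and any change of > 4 percentage points between
consecutive surviving samples (sequential scan against the last surviving
sample).

**Composite metrics** over valid samples: mean SpO2, minimum SpO2, morning
SpO2 (mean of the final hour), ΔSpO2 (second-half mean − first-half mean;
positive = overnight recovery), TST80 (% of valid window time with
SpO2 < 80%), and mean heart rate.

**Desaturation events.** An event is an excursion below a local baseline
(maximum of the preceding 30 s) satisfying rate (mean onset→nadir slope
> 0.1 %/s), magnitude (nadir ≥ 2 points below baseline), re-saturation
(ends at the first rise to baseline − 1 or nadir + 3, whichever first) and
duration (10–60 s inclusive). Per night this yields the oxygen desaturation
index ODI = events/h, mean event duration, and the hypoxic burden

    HB = (1/T) · Σ_events ∫ max(0, baseline − SpO2(t)) dt    [%·min/h]

**Statistics.** Two-group comparisons are routed by Shapiro–Wilk normality
(α = 0.05) to Student's t-test (mean ± SD) or Mann–Whitney U
(median [IQR]). Each nocturnal variable is assessed as a predictor of
morning AMS (Lake Louise total ≥ 3 with headache ≥ 1) via the rank-statistic
ROC AUC, a 95% percentile CI from 10,000 stratified bootstrap replicates,
the "better than random" rule (CI lower bound > 0.5), and — for flagged
predictors — the Youden-optimal threshold J = max(sens + spec − 1) in raw
units.

**Synthetic cohorts.** `noxim.simulate` generates complete studies — quantized
3 Hz traces with Poisson-placed desaturation events, half-night drift, bursty
sensor artifacts, ground-truth event ledgers, questionnaires, and an AMS
outcome logistically coupled to realized mean SpO2 — so every stage of the
pipeline is testable without any external data, and detector performance can
be scored against known truth.

## Worked example

```
$ noxim simulate --out demo/cohort --seed 7 --n-per-group 12
wrote cohort metadata to demo/cohort/participants.csv

$ noxim analyze --input demo/cohort --out demo/results --seed 7
analyzed 24 participants (0 excluded); reports in demo/results
predictors better than random:
    pre-term  mean_spo2            AUC 0.971 (0.857-1.000)
    pre-term  min_spo2             AUC 0.843 (0.586-1.000)
    pre-term  tst80                AUC 0.929 (0.786-1.000)
```

The simulated pre-term group carries an SpO2-coupled AMS outcome while the
term-born group does not, so saturation-level predictors are flagged as
better than random only in the pre-term stratum — mean SpO2 separates AMS+
from AMS− mornings with AUC 0.971 here, and no desaturation-frequency
metric is flagged. `demo/results/` contains per-participant metrics
(`metrics.csv`, one row per night: mean/min/morning SpO2, ΔSpO2, TST80,
heart rate, event count, ODI, duration, burden, valid fraction), per-event
ledgers (`events/*.csv`), the normality-routed group comparison table, the
full predictor × stratum ROC table, and a manifest with seed, version and
config hash. The same workflow applied to real recordings only needs the
trace files (`elapsed_s,spo2_pct,hr_bpm`; column names remappable in the
config) and a `participants.csv` with group labels and Lake Louise item
scores.

## Layout

```
src/noxim/trace.py      ingestion, analysis window, artifact masking
src/noxim/metrics.py    composite nocturnal variables
src/noxim/desat.py      desaturation detection, areas, ODI/burden
src/noxim/stats.py      questionnaires, routed comparisons, ROC/bootstrap/Youden
src/noxim/simulate.py   synthetic cohort generator + ground-truth ledgers
src/noxim/pipeline.py   end-to-end orchestration and reports
src/noxim/cli.py        noxim simulate | analyze | report
docs/methods.md         model assumptions, parameter choices, limitations
```
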