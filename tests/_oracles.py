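"""Independent reference implementations used only to cross-check the package.

Everything here is written as plainly as possible (python loops, explicit
slices) and stays independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def oracle_detect(values, valid, fs, p):
    """Naive desaturation scan applying the four criteria sample by sample.

    Returns a list of (onset, nadir, end, baseline) tuples. Semantics: onset
    is a valid sample followed by a strict decline; baseline is the max of
    the preceding lookback seconds of the valid segment (onset included); the
    running minimum after onset is the nadir; a sample strictly above the
    running minimum ends the event if it reaches baseline - margin or
    nadir + rise; accept iff depth >= min_depth, duration within bounds
    (inclusive) and mean onset->nadir slope > min_rate; resume after the end
    of an accepted event, else one sample past the failed onset. Candidates
    never cross invalid samples.
    """
    events = []
    n = len(values)
    look = int(round(p.baseline_lookback_s * fs))

    # contiguous valid segments
    segments = []
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            segments.append((i, j - 1))
            i = j
        else:
            i += 1

    for (s, t) in segments:
        o = s
        while o < t:
            accepted = False
            if values[o + 1] < values[o]:
                base = max(values[max(s, o - look) : o + 1])
                nadir_val, nadir_idx = values[o + 1], o + 1
                end = None
                for j in range(o + 2, t + 1):
                    v = values[j]
                    if v < nadir_val:
                        nadir_val, nadir_idx = v, j
                    elif v > nadir_val and (
                        v >= base - p.resat_baseline_margin
                        or v >= nadir_val + p.resat_nadir_rise
                    ):
                        end = j
                        break
                if end is not None:
                    depth = base - nadir_val
                    dur = (end - o) / fs
                    rate = depth / ((nadir_idx - o) / fs)
                    if (
                        depth >= p.min_depth
                        and p.min_dur <= dur <= p.max_dur
                        and rate > p.min_rate
                    ):
                        events.append((o, nadir_idx, end, base))
                        o = end + 1
                        accepted = True
            if not accepted:
                o += 1
    return events


def oracle_jump_scan(values, valid, max_step):
    """Survivor-based jump scan, list flavour."""
    out = list(valid)
    ref = None
    for i, v in enumerate(values):
        if not out[i]:
            continue
        if ref is None:
            ref = v
        elif abs(v - ref) > max_step:
            out[i] = False
        else:
            ref = v
    return out


def oracle_auc(values, outcome):
    """Exhaustive pairwise AUC with half-credit ties (higher = positive)."""
    cases = [v for v, y in zip(values, outcome) if y]
    controls = [v for v, y in zip(values, outcome) if not y]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def oracle_best_youden(values, outcome):
    """Max J over every possible cutpoint, by brute force (higher = positive)."""
    xs = sorted(set(values))
    cands = [-np.inf] + [(a + b) / 2 for a, b in zip(xs[:-1], xs[1:])] + [np.inf]
    best = -np.inf
    for c in cands:
        sens = np.mean([v > c for v, y in zip(values, outcome) if y])
        spec = np.mean([v <= c for v, y in zip(values, outcome) if not y])
        best = max(best, sens + spec - 1.0)
    return best
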