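"""Numerical inner loops for artifact scanning and desaturation detection.

Both kernels are plain sequential scans; numba compiles them when available so
whole-night 3 Hz traces (and multi-replicate simulations) stay fast. The
pure-Python definitions are the reference semantics and are used unchanged if
numba is not importable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def jump_scan(values, valid, max_step):
    """Sequential left-to-right jump-artifact scan.

    A valid sample differing by strictly more than ``max_step`` percentage
    points from the last *surviving* valid sample is invalidated; scanning
    continues against the same survivor. Single pass, idempotent.
    """
    n = values.shape[0]
    out = valid.copy()
    have_ref = False
    ref = 0.0
    for i in range(n):
        if not out[i]:
            continue
        if not have_ref:
            ref = values[i]
            have_ref = True
            continue
        if abs(values[i] - ref) > max_step:
            out[i] = False
        else:
            ref = values[i]
    return out


@njit(cache=False)
def detect_scan(
    values,
    valid,
    fs,
    min_rate,
    min_depth,
    resat_baseline_margin,
    resat_nadir_rise,
    min_dur,
    max_dur,
    lookback_s,
):
    """Scan for desaturation events; returns (count, onset, nadir, end, baseline).

    Criteria per event, evaluated within one contiguous valid segment:

    * onset ``o`` is a sample followed by a strict decline;
    * baseline is the maximum of the preceding ``lookback_s`` of valid signal
      (onset sample included), confined to the segment;
    * the nadir is the earliest running minimum after onset; the
      re-saturation rules apply only to samples strictly above the running
      nadir (a rise), so neither new lows nor flat dwells terminate;
    * the event ends at the first rising sample reaching
      ``baseline - resat_baseline_margin`` or ``nadir + resat_nadir_rise``,
      whichever occurs first in time;
    * accepted iff depth >= min_depth, min_dur <= duration <= max_dur
      (inclusive) and mean onset->nadir descent rate > min_rate;
    * scanning resumes after the end of an accepted event, one sample past a
      failed onset otherwise. Events never bridge invalid-sample gaps.
    """
    n = values.shape[0]
    cap = n // max(1, int(min_dur * fs)) + 2
    ev_onset = np.empty(cap, dtype=np.int64)
    ev_nadir = np.empty(cap, dtype=np.int64)
    ev_end = np.empty(cap, dtype=np.int64)
    ev_base = np.empty(cap, dtype=np.float64)
    k = 0
    look = int(round(lookback_s * fs))

    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        s = i
        while i < n and valid[i]:
            i += 1
        t = i - 1  # inclusive end of valid segment

        o = s
        while o < t:
            if values[o + 1] < values[o]:
                lb = o - look
                if lb < s:
                    lb = s
                b = values[lb]
                for q in range(lb + 1, o + 1):
                    if values[q] > b:
                        b = values[q]

                m_val = values[o + 1]
                m_idx = o + 1
                e = -1
                j = o + 2
                while j <= t:
                    vj = values[j]
                    if vj < m_val:
                        m_val = vj
                        m_idx = j
                    elif vj > m_val and (
                        vj >= b - resat_baseline_margin
                        or vj >= m_val + resat_nadir_rise
                    ):
                        e = j
                        break
                    j += 1

                if e >= 0:
                    depth = b - m_val
                    dur = (e - o) / fs
                    rate = depth / ((m_idx - o) / fs)
                    if (
                        depth >= min_depth
                        and dur >= min_dur
                        and dur <= max_dur
                        and rate > min_rate
                    ):
                        ev_onset[k] = o
                        ev_nadir[k] = m_idx
                        ev_end[k] = e
                        ev_base[k] = b
                        k += 1
                        o = e + 1
                        continue
            o += 1
    return k, ev_onset[:k], ev_nadir[:k], ev_end[:k], ev_base[:k]
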