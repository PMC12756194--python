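"""Independent reference implementations used as oracles by the tests.

These are deliberately naive (sample-by-sample loops, manual order-statistic
interpolation) and share no code with the package's vectorized paths.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_spike_scan(x, fs_hz, sigma, k_sigma=5.0, refractory_ms=20.0):
    """Loop-based spike detector: threshold every sample, merge by refractory.

    Returns a list of (onset_s, peak_amp_uv, duration_s) tuples.
    """
    thr = k_sigma * sigma
    refr_n = int(round(refractory_ms * 1e-3 * fs_hz))
    spans = []  # [start, end_exclusive]
    cur = None
    for i in range(len(x)):
        if abs(x[i]) >= thr:
            if cur is not None and i - cur[1] <= refr_n:
                cur[1] = i + 1
            else:
                if cur is not None:
                    spans.append(cur)
                cur = [i, i + 1]
    if cur is not None:
        spans.append(cur)
    out = []
    for a, b in spans:
        peak = max(abs(x[j]) for j in range(a, b))
        out.append((a / fs_hz, peak, (b - a) / fs_hz))
    return out


def sort_based_quartiles(values):
    """Manual linear-interpolation quantiles: (q2, p25, p75, max)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def pct(p):
        h = (n - 1) * p
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return pct(0.5), pct(0.25), pct(0.75), xs[-1]


def match_events(true_onsets, det_onsets, tol_s):
    """Greedy one-to-one chronological matching; returns number of matches."""
    ti, di, matches = 0, 0, 0
    true_onsets = sorted(true_onsets)
    det_onsets = sorted(det_onsets)
    while ti < len(true_onsets) and di < len(det_onsets):
        d = det_onsets[di] - true_onsets[ti]
        if abs(d) <= tol_s:
            matches += 1
            ti += 1
            di += 1
        elif d < 0:
            di += 1
        else:
            ti += 1
    return matches


def dwell_spans(state, fs_hz, value=1):
    """(onset_s, duration_s) of each run of *value* in a 0/1 state sequence."""
    spans = []
    start = None
    for i, s in enumerate(state):
        if s == value and start is None:
            start = i
        elif s != value and start is not None:
            spans.append((start / fs_hz, (i - start) / fs_hz))
            start = None
    if start is not None:
        spans.append((start / fs_hz, (len(state) - start) / fs_hz))
    return spans
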