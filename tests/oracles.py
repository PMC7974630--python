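"""Brute-force reference implementations used only to check the real ones."""

from __future__ import annotations

import numpy as np


def brute_force_peaks(values, min_sep_bins=4):
    """Naive positive-peak finder and splitter, written directly from the rules.

    Returns a list of dicts with start, end (inclusive), max_bin, max_value
    and sum over each peak.  Runs are scanned index by index; local maxima are
    checked plateau-wise against the raw definition; splits happen at the
    leftmost minimum strictly between consecutive qualifying maxima, the
    minimum bin going to the left peak.
    """
    values = list(values)
    n = len(values)
    # 1. maximal runs of strictly positive values, found by plain scanning
    runs = []
    i = 0
    while i < n:
        if values[i] > 0:
            j = i
            while j + 1 < n and values[j + 1] > 0:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    peaks = []
    for lo, hi in runs:
        # 2. plateau-aware local maxima (leftmost bin of each plateau)
        maxima = []
        k = lo
        while k <= hi:
            m = k
            while m + 1 <= hi and values[m + 1] == values[k]:
                m += 1
            higher_left = k > lo and values[k - 1] > values[k]
            equal_left = k > lo and values[k - 1] == values[k]
            higher_right = m < hi and values[m + 1] > values[k]
            if not higher_left and not equal_left and not higher_right:
                maxima.append(k)
            k = m + 1
        # 3. split between consecutive maxima at distance >= min_sep_bins
        cut_after = []
        for a, b in zip(maxima, maxima[1:]):
            if b - a >= min_sep_bins:
                best = None
                for c in range(a + 1, b):
                    if best is None or values[c] < values[best]:
                        best = c
                cut_after.append(best)
        starts = [lo] + [c + 1 for c in cut_after]
        ends = [c for c in cut_after] + [hi]
        for s, e in zip(starts, ends):
            seg = values[s : e + 1]
            mval = max(seg)
            peaks.append(
                {
                    "start": s,
                    "end": e,
                    "max_bin": s + seg.index(mval),
                    "max_value": mval,
                    "sum": float(np.sum(seg)),
                }
            )
    return peaks
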