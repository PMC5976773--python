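"""Independent brute-force oracles used to cross-check the package.

These deliberately reimplement the contracts sample by sample in plain
Python, sharing no code with the implementations they check.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np


def naive_rolling_std(x: Sequence[float], window: int) -> List[float]:
    """Centered rolling population SD, window truncated at the ends."""
    x = list(map(float, x))
    n = len(x)
    if window >= n:
        mu = sum(x) / n
        g = math.sqrt(sum((v - mu) ** 2 for v in x) / n)
        return [g] * n
    half = window // 2
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i - half + window)
        seg = x[lo:hi]
        mu = sum(seg) / len(seg)
        out.append(math.sqrt(sum((v - mu) ** 2 for v in seg) / len(seg)))
    return out


def naive_detect(x: Sequence[float], thresholds: Sequence[float],
                 dead_samples: float, polarity: str) -> List[int]:
    """Exhaustive per-sample scan: group contiguous supra-threshold samples
    into excursions, timestamp each at its extremum, then greedily drop
    events within the dead time of the last kept one."""
    x = list(map(float, x))
    above = []
    for v, t in zip(x, thresholds):
        if polarity == "negative":
            above.append(v < -t)
        elif polarity == "positive":
            above.append(v > t)
        else:
            above.append(abs(v) > t)
    events = []
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            seg = x[i:j + 1]
            if polarity == "negative":
                ext = min(range(len(seg)), key=lambda m: seg[m])
            elif polarity == "positive":
                ext = max(range(len(seg)), key=lambda m: seg[m])
            else:
                ext = max(range(len(seg)), key=lambda m: abs(seg[m]))
            events.append(i + ext)
            i = j + 1
        else:
            i += 1
    kept: List[int] = []
    for e in events:
        if not kept or e - kept[-1] >= dead_samples:
            kept.append(e)
    return kept


def naive_candidate_peaks(x: Sequence[float]) -> List[Tuple[int, int, int]]:
    """Brute-force peak delimitation: test every index for (plateau) local
    maximum status, collapse plateaus to their midpoint, and walk strictly
    decreasing flanks one sample at a time."""
    x = list(map(float, x))
    n = len(x)
    triples = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        is_max = i > 0 and j < n - 1 and x[i - 1] < x[i] and x[j + 1] < x[i]
        if is_max:
            peak = i + (j - i) // 2
            a = i
            while a - 1 >= 0 and x[a - 1] < x[a]:
                a -= 1
            b = j
            while b + 1 < n and x[b + 1] < x[b]:
                b += 1
            if a < peak < b:
                triples.append((a, peak, b))
        i = j + 1
    return triples


def naive_count_in_rect(points, x0, y0, w, h) -> int:
    c = 0
    for (x, y) in points:
        if not (math.isfinite(x) and math.isfinite(y)):
            continue
        if x0 <= x < x0 + w and y0 <= y < y0 + h:
            c += 1
    return c


def match_events(truth: np.ndarray, detected: np.ndarray, tol_s: float):
    """Greedy one-to-one matching within a tolerance; returns (tp, fp, fn)."""
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        if detected.size:
            d = np.abs(detected - t)
            ok = np.flatnonzero((d <= tol_s) & ~used)
            if ok.size:
                used[ok[np.argmin(d[ok])]] = True
                tp += 1
    return tp, int(detected.size - tp), int(truth.size - tp)
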