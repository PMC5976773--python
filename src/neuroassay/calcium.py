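"""Calcium-transient event calling on ROI fluorescence traces.

Candidate peaks are strict local maxima delimited by the furthest
monotonically (strictly) decreasing sample on each flank. Each candidate
is scored by the area of the triangle whose vertices are the peak and the
two flank minima; a peak is "relevant" when its area exceeds a
one-standard-deviation threshold (three interchangeable readings of that
rule are shipped, see :data:`RELEVANCE_RULES`). Relevant peaks drive the
per-cell event frequency, and only active cells (>= 1 relevant event)
enter group analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceTrace",
    "PeakCall",
    "EventFrequencyResult",
    "background_subtract",
    "find_candidate_peaks",
    "peak_relevance_area",
    "under_curve_area",
    "call_relevant_peaks",
    "event_frequency",
    "active_cell_filter",
    "RELEVANCE_RULES",
]


@dataclass
class FluorescenceTrace:
    """One ROI's fluorescence time series (arbitrary units)."""

    values: np.ndarray
    dt: float = 1.0
    roi_id: str = "roi_0"
    well_id: str = "well0"
    line: str = ""
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def duration_s(self) -> float:
        return self.values.size * self.dt


@dataclass
class PeakCall:
    """A delimited candidate peak with its relevance score."""

    peak_index: int
    left_min_index: int
    right_min_index: int
    amplitude: float
    relevance_area: float
    is_relevant: bool = False

    def __post_init__(self) -> None:
        if not (self.left_min_index < self.peak_index < self.right_min_index):
            raise ValueError("need left_min_index < peak_index < right_min_index")
        if self.relevance_area < 0:
            raise ValueError("relevance_area must be >= 0")


@dataclass
class EventFrequencyResult:
    roi_id: str
    n_relevant_events: int
    frequency_per_min: float
    active: bool


def background_subtract(trace: FluorescenceTrace, background) -> FluorescenceTrace:
    """Subtract a scalar or same-length background; sets the provenance flag."""
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 0:
        vals = trace.values - float(bg)
    elif bg.shape == trace.values.shape:
        vals = trace.values - bg
    else:
        raise ValueError(
            f"background length {bg.size} does not match trace length {trace.values.size}")
    out = replace(trace)
    out.values = vals
    out.background_subtracted = True
    return out


def _plateau_maxima(x: np.ndarray) -> List[Tuple[int, int]]:
    """(left_edge, right_edge) of every interior local maximum, where a
    plateau of equal samples counts once. Edges of the trace never qualify."""
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def find_candidate_peaks(trace: FluorescenceTrace) -> List[Tuple[int, int, int]]:
    """Delimit candidate peaks as (left_min, peak, right_min) index triples.

    Peaks are strict local maxima (plateaus collapse to their midpoint,
    left of center when even). From each peak the flank is walked outward
    while every next sample is strictly lower than the previous; the flank
    minimum is the last sample of that strict descent. Peaks lacking a
    descent on either side are discarded.
    """
    if not trace.background_subtracted:
        warnings.warn("peak finding on a trace without background subtraction "
                      "provenance", stacklevel=2)
    x = trace.values
    if x.size < 3:
        raise ValueError("need at least 3 samples for peak calling")
    triples = []
    for left_edge, right_edge in _plateau_maxima(x):
        peak = left_edge + (right_edge - left_edge) // 2
        j = left_edge
        while j - 1 >= 0 and x[j - 1] < x[j]:
            j -= 1
        k = right_edge
        while k + 1 <= x.size - 1 and x[k + 1] < x[k]:
            k += 1
        if j < peak < k:
            triples.append((j, peak, k))
    return triples


def peak_relevance_area(trace: FluorescenceTrace, triple: Tuple[int, int, int]) -> float:
    """Triangle (shoelace) area of the three vertices, in a.u. * seconds.

    Invariant to vertical offset and time translation; degenerate
    (collinear) vertices give 0.
    """
    left, peak, right = triple
    if not (0 <= left < peak < right < trace.values.size):
        raise ValueError(f"invalid triple {triple} for trace of length {trace.values.size}")
    t = np.array([left, peak, right], dtype=float) * trace.dt
    y = trace.values[[left, peak, right]]
    area = 0.5 * abs(t[0] * (y[1] - y[2]) + t[1] * (y[2] - y[0]) + t[2] * (y[0] - y[1]))
    return float(area)


def under_curve_area(trace: FluorescenceTrace, triple: Tuple[int, int, int]) -> float:
    """Alternative score: trapezoidal area under the trace between the two
    flank minima, above the chord's lower vertex level."""
    left, peak, right = triple
    seg = trace.values[left:right + 1]
    base = min(seg[0], seg[-1])
    return float(np.trapezoid(seg - base, dx=trace.dt))


def _threshold_signal(trace: FluorescenceTrace, areas: Sequence[float],
                      sd_multiplier: float) -> float:
    # population SD of the trace samples
    return float(np.mean(trace.values) + sd_multiplier * np.std(trace.values))


def _threshold_peak_population(trace: FluorescenceTrace, areas: Sequence[float],
                               sd_multiplier: float) -> float:
    a = np.asarray(areas, dtype=float)
    return float(np.mean(a) + sd_multiplier * np.std(a))


def _threshold_signal_sd_only(trace: FluorescenceTrace, areas: Sequence[float],
                              sd_multiplier: float) -> float:
    return float(sd_multiplier * np.std(trace.values))


#: Pluggable readings of "area greater than one standard deviation from the
#: mean of the signal". "literal" (default): area > mean(trace) + SD(trace).
RELEVANCE_RULES: Dict[str, Callable] = {
    "literal": _threshold_signal,
    "peak_population": _threshold_peak_population,
    "sd_only": _threshold_signal_sd_only,
}

#: Pluggable area functionals for scoring a delimited peak.
AREA_FUNCTIONALS: Dict[str, Callable] = {
    "triangle": peak_relevance_area,
    "under_curve": under_curve_area,
}


def call_relevant_peaks(trace: FluorescenceTrace, rule: str = "literal",
                        sd_multiplier: float = 1.0,
                        area: str = "triangle") -> List[PeakCall]:
    """Score every candidate peak and flag those above the relevance
    threshold. All candidates are returned (with their areas) so callers
    can re-threshold without re-delimiting."""
    if rule not in RELEVANCE_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(RELEVANCE_RULES)}")
    if area not in AREA_FUNCTIONALS:
        raise ValueError(f"unknown area functional {area!r}")
    if rule == "literal" and trace.dt != 1.0:
        warnings.warn("literal relevance rule compares an area (a.u.*s) to an "
                      "amplitude statistic; with dt != 1 s the units diverge",
                      stacklevel=2)
    triples = find_candidate_peaks(trace)
    if not triples:
        return []
    areas = [AREA_FUNCTIONALS[area](trace, tr) for tr in triples]
    thr = RELEVANCE_RULES[rule](trace, areas, sd_multiplier)
    return [PeakCall(peak_index=p, left_min_index=l, right_min_index=r,
                     amplitude=float(trace.values[p]), relevance_area=a,
                     is_relevant=bool(a > thr))
            for (l, p, r), a in zip(triples, areas)]


def event_frequency(peakcalls: Sequence[PeakCall], duration_s: float,
                    roi_id: str = "roi_0") -> EventFrequencyResult:
    """Events/min from relevant peaks only; active means >= 1 relevant event."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = sum(1 for p in peakcalls if p.is_relevant)
    return EventFrequencyResult(roi_id=roi_id, n_relevant_events=n,
                                frequency_per_min=n / (duration_s / 60.0),
                                active=n >= 1)


def active_cell_filter(results: Sequence[EventFrequencyResult]) -> List[EventFrequencyResult]:
    """Keep active cells only; the number excluded is logged."""
    kept = [r for r in results if r.active]
    logger.info("active_cell_filter: kept %d of %d cells (%d inactive excluded)",
                len(kept), len(results), len(results) - len(kept))
    return kept
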