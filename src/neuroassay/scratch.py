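"""Scratch-assay reinvasion quantification.

Counts objects (cell bodies and processes) inside the standardized
1.3 x 0.35 mm region daily over the ten-day recovery, and summarizes
repopulation as raw counts, densities and a least-squares recovery rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ScratchROI",
    "ScratchSeries",
    "count_in_roi",
    "reinvasion_timecourse",
    "recovery_rate",
]


@dataclass(frozen=True)
class ScratchROI:
    """Standardized counting region, in mm."""

    width_mm: float = 1.3
    height_mm: float = 0.35
    origin_mm: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("ROI width and height must be > 0")

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.height_mm


@dataclass
class ScratchSeries:
    """Daily object counts inside the ROI for one well."""

    well_id: str
    group: str
    days: np.ndarray
    counts: np.ndarray
    roi: ScratchROI = field(default_factory=ScratchROI)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.days.size != self.counts.size:
            raise ValueError("days and counts must have equal length")
        if np.unique(self.days).size != self.days.size or np.any(np.diff(self.days) < 0):
            raise ValueError("days must be unique and sorted ascending")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


def count_in_roi(objects: Sequence[Tuple[float, float]], roi: ScratchROI) -> int:
    """Number of objects with x in [x0, x0+width) and y in [y0, y0+height).

    Half-open on both axes so tiling ROIs never double-count. Records with
    non-finite coordinates are skipped (count logged), not fatal.
    """
    x0, y0 = roi.origin_mm
    n = skipped = 0
    for xy in objects:
        x, y = float(xy[0]), float(xy[1])
        if not (math.isfinite(x) and math.isfinite(y)):
            skipped += 1
            continue
        if x0 <= x < x0 + roi.width_mm and y0 <= y < y0 + roi.height_mm:
            n += 1
    if skipped:
        logger.info("count_in_roi: skipped %d record(s) with non-finite coordinates",
                    skipped)
    return n


def reinvasion_timecourse(series: ScratchSeries) -> pd.DataFrame:
    """Raw counts, density per mm^2 and counts normalized to the final
    day's value, with no smoothing. Normalization is NaN when the final
    count is zero."""
    if series.days.size < 2:
        raise ValueError("need at least 2 days")
    counts = series.counts.astype(float)
    final = counts[-1]
    normalized = counts / final if final > 0 else np.full_like(counts, np.nan)
    return pd.DataFrame({
        "well": series.well_id,
        "group": series.group,
        "day": series.days,
        "count": series.counts,
        "density_per_mm2": counts / series.roi.area_mm2,
        "normalized": normalized,
    })


def recovery_rate(series: ScratchSeries, ci: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """Least-squares slope of count vs day (objects/day) with a CI from
    the slope's standard error."""
    if series.days.size < 3:
        raise ValueError("need at least 3 days for a recovery rate")
    x = series.days.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: all observations on one day")
    res = sps.linregress(x, series.counts.astype(float))
    tcrit = sps.t.ppf(0.5 + ci / 2, df=x.size - 2)
    half = tcrit * res.stderr
    return float(res.slope), (float(res.slope - half), float(res.slope + half))
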