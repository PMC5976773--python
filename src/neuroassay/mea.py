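"""Multi-electrode-array signal chain.

Band-pass filtering (first-order Butterworth, 200-2500 Hz by default),
adaptive spike thresholding at a multiple of the rolling standard
deviation of the filtered trace, and per-well firing-rate summaries from
ten-minute recordings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "VoltageTrace",
    "FilterSpec",
    "ThresholdSpec",
    "SpikeTrain",
    "WellActivitySummary",
    "bandpass_filter",
    "analog_bandpass_gain",
    "rolling_std",
    "detect_spikes",
    "well_spike_rate",
    "export_raster",
    "read_raster",
]


@dataclass
class VoltageTrace:
    """One electrode's extracellular voltage signal in µV."""

    samples: np.ndarray
    fs: float = 12500.0
    electrode_id: str = "e00"
    well_id: str = "well0"
    filtered: bool = False  # provenance flag set by bandpass_filter

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Software band-pass: first-order Butterworth, 200-2500 Hz."""

    low_hz: float = 200.0
    high_hz: float = 2500.0
    order: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_against(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz is at or above Nyquist ({fs / 2} Hz)")


@dataclass(frozen=True)
class ThresholdSpec:
    """Adaptive threshold: k times the rolling SD of the filtered trace.

    Window length, dead time and polarity are free parameters (not fixed
    by the source protocol); defaults are 100 ms, 1 ms, bipolar.
    """

    k: float = 5.25
    window_s: float = 0.1
    dead_time_s: float = 1e-3
    polarity: str = "both"  # {"negative", "positive", "both"}

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be >= 0")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class SpikeTrain:
    """Detected spike timestamps (seconds from recording start) for one
    electrode, with the threshold rule that produced them."""

    timestamps: np.ndarray
    electrode_id: str
    well_id: str = "well0"
    duration_s: float = 0.0
    k: float = 5.25
    window_s: float = 0.1
    dead_time_s: float = 1e-3

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size:
            if np.any(np.diff(self.timestamps) < 0):
                raise ValueError("timestamps must be sorted ascending")
            if self.duration_s and (self.timestamps[0] < 0
                                    or self.timestamps[-1] > self.duration_s):
                raise ValueError("timestamps outside [0, duration]")
            if self.dead_time_s > 0 and self.timestamps.size > 1:
                if np.min(np.diff(self.timestamps)) < self.dead_time_s - 1e-12:
                    raise ValueError("timestamps violate dead time")

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass
class WellActivitySummary:
    """Per-well firing summary: all-electrode mean and active-only mean."""

    well_id: str
    electrode_rates_hz: dict
    well_mean_rate_hz: float
    active_mean_rate_hz: float
    active_electrode_count: int
    n_electrodes: int


def _sos(spec: FilterSpec, fs: float) -> np.ndarray:
    return signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                         btype="bandpass", fs=fs, output="sos")


def bandpass_filter(trace: VoltageTrace, spec: FilterSpec = FilterSpec()) -> VoltageTrace:
    """Apply the digital (bilinear-transform) Butterworth band-pass.

    Same-length output; DC is rejected exactly (zero at z = 1) and the
    gain at the two cutoffs is -3 dB up to discretization tolerance.
    """
    spec.validate_against(trace.fs)
    y = signal.sosfilt(_sos(spec, trace.fs), trace.samples)
    return VoltageTrace(samples=y, fs=trace.fs, electrode_id=trace.electrode_id,
                        well_id=trace.well_id, filtered=True)


def analog_bandpass_gain(f_hz, spec: FilterSpec = FilterSpec()):
    """Closed-form amplitude response |H(f)| of the analog first-order
    Butterworth band-pass with the spec's cutoffs.

    H(s) = B s / (s^2 + B s + w0^2), B = wh - wl, w0^2 = wl * wh.
    """
    if spec.order != 1:
        raise ValueError("closed form implemented for order 1 only")
    f = np.asarray(f_hz, dtype=float)
    wl, wh = 2 * np.pi * spec.low_hz, 2 * np.pi * spec.high_hz
    w = 2 * np.pi * f
    B, w0sq = wh - wl, wl * wh
    h = (1j * w * B) / ((1j * w) ** 2 + 1j * w * B + w0sq)
    return np.abs(h)


def rolling_std(trace: VoltageTrace | np.ndarray, window_s: float,
                fs: float | None = None) -> np.ndarray:
    """Per-sample rolling (population) SD over a centered window.

    The window is truncated where it overruns the trace ends, so the
    output has the input's length. If the window does not fit in the
    trace at all, falls back to the global SD (logged).
    """
    if isinstance(trace, VoltageTrace):
        x, fs = trace.samples, trace.fs
    else:
        x = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    n = x.size
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError(f"window of {window_s}s holds {w} sample(s); need >= 2")
    if w >= n:
        if w > n:
            logger.info("rolling_std window (%d samples) exceeds trace (%d); "
                        "falling back to global SD", w, n)
        return np.full(n, float(np.std(x)))
    half = w // 2
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx - half + w, None, n)
    cnt = (hi - lo).astype(float)
    m = (c1[hi] - c1[lo]) / cnt
    var = (c2[hi] - c2[lo]) / cnt - m * m
    return np.sqrt(np.clip(var, 0.0, None))


def _excursion_extrema(x: np.ndarray, above: np.ndarray, polarity: str) -> np.ndarray:
    """Index of the extremum of each contiguous supra-threshold excursion."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return idx
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    out = []
    for run in np.split(idx, breaks):
        seg = x[run]
        if polarity == "negative":
            out.append(run[np.argmin(seg)])
        elif polarity == "positive":
            out.append(run[np.argmax(seg)])
        else:
            out.append(run[np.argmax(np.abs(seg))])
    return np.asarray(out, dtype=int)


def _apply_dead_time(event_idx: np.ndarray, dead_samples: float) -> np.ndarray:
    if event_idx.size == 0 or dead_samples <= 0:
        return event_idx
    kept = [event_idx[0]]
    for i in event_idx[1:]:
        if i - kept[-1] >= dead_samples:
            kept.append(i)
    return np.asarray(kept, dtype=int)


def detect_spikes(filtered: VoltageTrace, tspec: ThresholdSpec = ThresholdSpec()) -> SpikeTrain:
    """Detect threshold crossings of k x rolling SD.

    One spike per contiguous supra-threshold excursion, timestamped at the
    excursion's extremum; later crossings within the dead time of a kept
    spike are suppressed. Empty trains are valid (silent electrodes).
    """
    if not filtered.filtered:
        warnings.warn("detect_spikes called on a trace without the band-pass "
                      "provenance flag; proceeding anyway", stacklevel=2)
    x = filtered.samples
    sd = rolling_std(x, tspec.window_s, fs=filtered.fs)
    thr = tspec.k * sd
    if tspec.polarity == "negative":
        above = x < -thr
    elif tspec.polarity == "positive":
        above = x > thr
    else:
        above = np.abs(x) > thr
    events = _excursion_extrema(x, above, tspec.polarity)
    events = _apply_dead_time(events, tspec.dead_time_s * filtered.fs)
    return SpikeTrain(timestamps=events / filtered.fs,
                      electrode_id=filtered.electrode_id,
                      well_id=filtered.well_id,
                      duration_s=filtered.duration_s,
                      k=tspec.k, window_s=tspec.window_s,
                      dead_time_s=tspec.dead_time_s)


def well_spike_rate(trains: Sequence[SpikeTrain], duration_s: float,
                    active_rate_min_per_min: float = 5.0) -> WellActivitySummary:
    """Per-electrode rates and well averages for one well's trains.

    The well mean is the arithmetic mean over every electrode passed in
    (silent ones included); an active-only mean (active = at least
    ``active_rate_min_per_min`` spikes per minute) is reported alongside.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if not trains:
        raise ValueError("need at least one spike train")
    wells = {t.well_id for t in trains}
    if len(wells) != 1:
        raise ValueError(f"trains span multiple wells: {sorted(wells)}")
    rates = {t.electrode_id: len(t) / duration_s for t in trains}
    vals = np.array(list(rates.values()))
    active_thr_hz = active_rate_min_per_min / 60.0
    active = vals >= active_thr_hz
    n_active = int(active.sum())
    active_mean = float(vals[active].mean()) if n_active else 0.0
    logger.info("well %s: %d/%d electrodes active", next(iter(wells)),
                n_active, len(trains))
    return WellActivitySummary(well_id=next(iter(wells)),
                               electrode_rates_hz=rates,
                               well_mean_rate_hz=float(vals.mean()),
                               active_mean_rate_hz=active_mean,
                               active_electrode_count=n_active,
                               n_electrodes=len(trains))


def export_raster(trains: Iterable[SpikeTrain]) -> pd.DataFrame:
    """Long-format spike timestamp table, electrode-major then time-major."""
    rows = []
    for t in trains:
        for ts in t.timestamps:
            rows.append((t.well_id, t.electrode_id, float(ts)))
    df = pd.DataFrame(rows, columns=["well", "electrode", "timestamp_s"])
    return df.sort_values(["well", "electrode", "timestamp_s"]).reset_index(drop=True)


def read_raster(df: pd.DataFrame, duration_s: float = 0.0,
                tspec: ThresholdSpec = ThresholdSpec(dead_time_s=0.0)) -> List[SpikeTrain]:
    """Inverse of :func:`export_raster` (lossless round-trip).

    External timestamp tables carry no dead-time provenance, so none is
    enforced unless a ThresholdSpec is supplied."""
    trains = []
    for (well, elec), g in df.groupby(["well", "electrode"], sort=True):
        trains.append(SpikeTrain(timestamps=np.sort(g["timestamp_s"].to_numpy()),
                                 electrode_id=str(elec), well_id=str(well),
                                 duration_s=duration_s, k=tspec.k,
                                 window_s=tspec.window_s,
                                 dead_time_s=tspec.dead_time_s))
    return trains
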