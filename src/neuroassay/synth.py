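"""Seeded synthetic-data generators for the three functional assays.

Produces ground-truth-labeled multi-electrode-array (MEA) voltage traces,
calcium fluorescence traces and scratch-assay reinvasion count series with
a case/control cohort structure, so the downstream detection and statistics
stages can be validated without any recorded data.

All randomness flows through a single :class:`numpy.random.Generator`
derived from ``SynthParams.seed``; the same parameters always produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np

from .mea import VoltageTrace
from .calcium import FluorescenceTrace

__all__ = [
    "SynthParams",
    "GroundTruth",
    "biphasic_template",
    "poisson_event_times",
    "simulate_mea_ground_truth",
    "simulate_mea_well",
    "simulate_calcium_cell",
    "scratch_mean_curve",
    "simulate_scratch_series",
    "simulate_cohort",
    "write_cohort",
    "Cohort",
]

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)


@dataclass(frozen=True)
class SynthParams:
    """Cohort- and signal-level parameters for the simulators.

    Control firing/event rates are free parameters (no published values
    exist); effect factors are the multiplicative suppression applied to
    the case group.
    """

    seed: int = 0
    # cohort layout
    n_case_lines: int = 6
    n_control_lines: int = 5
    wells_per_group: int = 16      # wells per cell line (spread over replicates)
    replicates: int = 3
    # MEA
    mea_rate_control: float = 2.0  # spikes/s per active electrode
    mea_effect: float = 0.5        # multiplicative rate factor for cases
    mea_fs: float = 12500.0
    mea_duration_s: float = 600.0
    n_electrodes: int = 64
    noise_sd: float = 10.0         # µV
    spike_amplitude_sd: float = 8.0  # spike trough depth as multiple of noise_sd
    silent_fraction: float = 0.5   # fraction of electrodes with zero rate
    # calcium
    ca_event_rate_control: float = 2.0  # events/min
    ca_effect: float = 0.5
    ca_dt: float = 1.0
    ca_duration_s: float = 600.0
    ca_amplitude: float = 5.0      # a.u., transient peak above baseline
    ca_tau_s: float = 2.0          # exponential decay constant
    ca_noise_sd: float = 0.5
    # resting-fluorescence floor; under the literal relevance rule it sets
    # the scale of the mean+SD threshold, so it must stay > 0
    ca_baseline: float = 3.0
    ca_drift_per_s: float = 0.0
    ca_rois_per_field: int = 10
    # scratch
    scratch_rate_control: float = 30.0  # mean new objects per day (control)
    scratch_effect: float = 0.5         # post-divergence case growth factor
    scratch_divergence_day: int = 4
    scratch_days: int = 10

    def __post_init__(self) -> None:
        counts = {
            "n_case_lines": self.n_case_lines,
            "n_control_lines": self.n_control_lines,
            "wells_per_group": self.wells_per_group,
            "replicates": self.replicates,
            "n_electrodes": self.n_electrodes,
            "ca_rois_per_field": self.ca_rois_per_field,
            "scratch_days": self.scratch_days,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        # event rates may be exactly 0 (empty-process traces are meaningful)
        for name, v in {
            "mea_rate_control": self.mea_rate_control,
            "ca_event_rate_control": self.ca_event_rate_control,
        }.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        rates = {
            "scratch_rate_control": self.scratch_rate_control,
            "mea_fs": self.mea_fs,
            "mea_duration_s": self.mea_duration_s,
            "ca_dt": self.ca_dt,
            "ca_duration_s": self.ca_duration_s,
            "ca_tau_s": self.ca_tau_s,
            "ca_amplitude": self.ca_amplitude,
        }
        for name, v in rates.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        for name, v in {
            "mea_effect": self.mea_effect,
            "ca_effect": self.ca_effect,
            "scratch_effect": self.scratch_effect,
        }.items():
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if not (0 <= self.silent_fraction <= 1):
            raise ValueError("silent_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.ca_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.scratch_divergence_day < 0:
            raise ValueError("scratch_divergence_day must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """True event times and effect parameters behind a simulated object."""

    spike_times: Dict[str, np.ndarray] = field(default_factory=dict)
    ca_event_times: Dict[str, np.ndarray] = field(default_factory=dict)
    effects: Dict[str, float] = field(default_factory=dict)

    def validate(self, duration_s: float) -> None:
        for d in (self.spike_times, self.ca_event_times):
            for key, t in d.items():
                t = np.asarray(t, dtype=float)
                if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > duration_s):
                    raise ValueError(f"ground-truth times for {key} not sorted within [0, {duration_s}]")


def _group_factor(group_label: str, effect: float) -> float:
    if group_label not in GROUPS:
        raise ValueError(f"group_label must be one of {GROUPS}, got {group_label!r}")
    return effect if group_label == CASE else 1.0


def poisson_event_times(rate_hz: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous-Poisson event times on [0, duration_s), sorted ascending."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if rate_hz == 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def biphasic_template(fs: float, duration_s: float = 1.6e-3,
                      trough_peak_ratio: float = 2.0) -> Tuple[np.ndarray, int]:
    """Extracellular-like biphasic spike template: negative trough then
    positive rebound, normalized so the trough equals -1.

    Returns (template, trough_index).
    """
    n = int(round(fs * duration_s))
    if n < 2:
        raise ValueError(
            f"sampling rate {fs} Hz cannot hold a {duration_s * 1e3:.2f} ms waveform")
    t = np.arange(n) / fs
    w = (-np.exp(-0.5 * ((t - 0.45e-3) / 0.15e-3) ** 2)
         + (1.0 / trough_peak_ratio) * np.exp(-0.5 * ((t - 0.95e-3) / 0.25e-3) ** 2))
    w /= -w.min()
    return w, int(np.argmin(w))


def simulate_mea_ground_truth(params: SynthParams, group_label: str,
                              rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Per-electrode true spike times for one well (no voltage rendering).

    A ``silent_fraction`` of electrodes gets rate 0; the rest fire as
    independent Poisson processes at the group-scaled control rate.
    """
    rate = params.mea_rate_control * _group_factor(group_label, params.mea_effect)
    silent = rng.random(params.n_electrodes) < params.silent_fraction
    out: Dict[str, np.ndarray] = {}
    for e in range(params.n_electrodes):
        r = 0.0 if silent[e] else rate
        out[f"e{e:02d}"] = poisson_event_times(r, params.mea_duration_s, rng)
    return out


def simulate_mea_well(params: SynthParams, group_label: str,
                      rng: np.random.Generator | None = None,
                      well_id: str = "well0") -> Tuple[List[VoltageTrace], GroundTruth]:
    """Simulate one MEA well: Gaussian noise plus biphasic waveforms at
    Poisson times on each electrode of the grid.

    Ground-truth spike times refer to the waveform trough (the extremum a
    detector should report).
    """
    if rng is None:
        rng = params.rng()
    template, trough = biphasic_template(params.mea_fs)
    wf_dur = template.size / params.mea_fs
    if params.mea_duration_s <= wf_dur:
        raise ValueError(
            f"duration {params.mea_duration_s}s cannot hold one {wf_dur * 1e3:.2f} ms waveform")
    n = int(round(params.mea_fs * params.mea_duration_s))
    amp = params.spike_amplitude_sd * params.noise_sd
    event_times = simulate_mea_ground_truth(params, group_label, rng)

    traces: List[VoltageTrace] = []
    gt = GroundTruth(effects={"mea_effect": _group_factor(group_label, params.mea_effect)})
    max_start = n - template.size
    for e in range(params.n_electrodes):
        eid = f"e{e:02d}"
        x = rng.normal(0.0, params.noise_sd, size=n)
        starts = np.round(event_times[eid] * params.mea_fs).astype(int)
        starts = starts[(starts >= 0) & (starts <= max_start)]
        for s in starts:
            x[s:s + template.size] += amp * template
        gt.spike_times[eid] = (starts + trough) / params.mea_fs
        traces.append(VoltageTrace(samples=x, fs=params.mea_fs,
                                   electrode_id=eid, well_id=well_id))
    gt.validate(params.mea_duration_s)
    return traces, gt


def simulate_calcium_cell(params: SynthParams, group_label: str,
                          rng: np.random.Generator | None = None,
                          roi_id: str = "roi_0") -> Tuple[FluorescenceTrace, GroundTruth]:
    """One ROI's fluorescence trace: baseline + optional drift + noise +
    instantaneous-rise / exponential-decay transients at Poisson times."""
    if rng is None:
        rng = params.rng()
    if params.ca_tau_s <= 0:
        raise ValueError("ca_tau_s must be > 0")
    if params.ca_amplitude <= 0:
        raise ValueError("ca_amplitude must be > 0")
    n = int(round(params.ca_duration_s / params.ca_dt))
    t = np.arange(n) * params.ca_dt
    rate_hz = (params.ca_event_rate_control / 60.0) * _group_factor(group_label, params.ca_effect)
    events = poisson_event_times(rate_hz, params.ca_duration_s, rng)
    x = params.ca_baseline + params.ca_drift_per_s * t
    if params.ca_noise_sd > 0:
        x = x + rng.normal(0.0, params.ca_noise_sd, size=n)
    # rise is sub-sample at 1 Hz and the camera integrates the frame, so the
    # transient peaks at full amplitude on the nearest sample
    for te in events:
        i0 = min(int(round(te / params.ca_dt)), n - 1)
        x[i0:] += params.ca_amplitude * np.exp(-(t[i0:] - t[i0]) / params.ca_tau_s)
    gt = GroundTruth(ca_event_times={roi_id: events},
                     effects={"ca_effect": _group_factor(group_label, params.ca_effect)})
    gt.validate(params.ca_duration_s)
    trace = FluorescenceTrace(values=x, dt=params.ca_dt, roi_id=roi_id)
    return trace, gt


def scratch_mean_curve(params: SynthParams, group_label: str) -> np.ndarray:
    """Expected reinvasion count per day (index 0..scratch_days).

    Case and control means are identical through ``scratch_divergence_day``;
    after it the case curve grows by ``scratch_effect`` of the control rate.
    """
    f = _group_factor(group_label, params.scratch_effect)
    days = np.arange(params.scratch_days + 1, dtype=float)
    d0 = float(params.scratch_divergence_day)
    r = params.scratch_rate_control
    mu = np.where(days <= d0, r * days, r * d0 + (f * r) * (days - d0))
    return mu


def simulate_scratch_series(params: SynthParams, group_label: str,
                            rng: np.random.Generator | None = None,
                            well_id: str = "well0"):
    """Poisson counts around the group's monotone mean reinvasion curve."""
    from .scratch import ScratchSeries, ScratchROI

    if rng is None:
        rng = params.rng()
    mu = scratch_mean_curve(params, group_label)
    counts = rng.poisson(mu)
    return ScratchSeries(well_id=well_id, group=group_label,
                         days=np.arange(params.scratch_days + 1),
                         counts=counts, roi=ScratchROI())


@dataclass
class Cohort:
    """In-memory simulated cohort: design table plus per-well data."""

    params: SynthParams
    design: "pandas.DataFrame"  # noqa: F821 - imported lazily
    mea_ground_truth: Dict[str, Dict[str, np.ndarray]]
    mea_traces: Dict[str, List[VoltageTrace]]
    calcium: Dict[str, List[FluorescenceTrace]]
    ca_ground_truth: Dict[str, Dict[str, np.ndarray]]
    scratch: Dict[str, "ScratchSeries"]  # noqa: F821


def _line_labels(params: SynthParams) -> List[Tuple[str, str]]:
    lines = [(f"case{i + 1:02d}", CASE) for i in range(params.n_case_lines)]
    lines += [(f"ctrl{i + 1:02d}", CONTROL) for i in range(params.n_control_lines)]
    return lines


def simulate_cohort(params: SynthParams, render_voltage: bool = True) -> Cohort:
    """Simulate the full cohort: per line, ``wells_per_group`` MEA wells
    (replicate labels assigned round-robin), one calcium imaging field per
    line x replicate, and one scratch series per line x replicate.

    With ``render_voltage=False`` only MEA ground-truth spike times are
    generated (fast path for statistics at full scale).
    """
    import pandas as pd

    rng = params.rng()
    rows = []
    mea_gt: Dict[str, Dict[str, np.ndarray]] = {}
    mea_traces: Dict[str, List[VoltageTrace]] = {}
    calcium: Dict[str, List[FluorescenceTrace]] = {}
    ca_gt: Dict[str, Dict[str, np.ndarray]] = {}
    scratch: Dict[str, object] = {}

    for line, group in _line_labels(params):
        for w in range(params.wells_per_group):
            rep = (w % params.replicates) + 1
            wid = f"{line}_w{w:02d}"
            rows.append({"well_or_cell": wid, "line": line, "group": group,
                         "replicate": rep, "assay": "mea"})
            if render_voltage:
                traces, gt = simulate_mea_well(params, group, rng, well_id=wid)
                mea_traces[wid] = traces
                mea_gt[wid] = gt.spike_times
            else:
                mea_gt[wid] = simulate_mea_ground_truth(params, group, rng)
        for rep in range(1, params.replicates + 1):
            fid = f"{line}_ca_r{rep}"
            rows.append({"well_or_cell": fid, "line": line, "group": group,
                         "replicate": rep, "assay": "calcium"})
            field_traces, field_gt = [], {}
            for k in range(params.ca_rois_per_field):
                tr, gt = simulate_calcium_cell(params, group, rng, roi_id=f"roi_{k}")
                field_traces.append(tr)
                field_gt[f"roi_{k}"] = gt.ca_event_times[f"roi_{k}"]
            calcium[fid] = field_traces
            ca_gt[fid] = field_gt
            sid = f"{line}_sc_r{rep}"
            rows.append({"well_or_cell": sid, "line": line, "group": group,
                         "replicate": rep, "assay": "scratch"})
            scratch[sid] = simulate_scratch_series(params, group, rng, well_id=sid)

    design = pd.DataFrame(rows)
    return Cohort(params=params, design=design, mea_ground_truth=mea_gt,
                  mea_traces=mea_traces, calcium=calcium,
                  ca_ground_truth=ca_gt, scratch=scratch)


def write_cohort(cohort: Cohort, out_dir, force: bool = False) -> None:
    """Write the cohort as plain CSV tables plus a JSON ground-truth file.

    Layout: ``design.csv``, ``mea/<well>.csv`` (time_s, e00..), one
    ``calcium/<field>.csv`` (time_s, roi_0..), ``scratch_counts.csv`` and
    ``ground_truth.json``. Refuses to reuse a non-empty directory unless
    ``force``.
    """
    import json
    from pathlib import Path
    import pandas as pd

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output path {out} exists and is not empty (use force=True)")
    (out / "mea").mkdir(parents=True, exist_ok=True)
    (out / "calcium").mkdir(parents=True, exist_ok=True)

    cohort.design.to_csv(out / "design.csv", index=False)

    p = cohort.params
    for wid, traces in cohort.mea_traces.items():
        n = traces[0].samples.size
        cols = {"time_s": np.arange(n) / p.mea_fs}
        for tr in traces:
            cols[tr.electrode_id] = tr.samples
        pd.DataFrame(cols).to_csv(out / "mea" / f"{wid}.csv", index=False,
                                  float_format="%.4f")
    for fid, traces in cohort.calcium.items():
        n = traces[0].values.size
        cols = {"time_s": np.arange(n) * p.ca_dt}
        for tr in traces:
            cols[tr.roi_id] = tr.values
        pd.DataFrame(cols).to_csv(out / "calcium" / f"{fid}.csv", index=False,
                                  float_format="%.6f")
    sc_rows = []
    for sid, series in cohort.scratch.items():
        for d, c in zip(series.days, series.counts):
            sc_rows.append({"well": sid, "day": int(d), "count": int(c)})
    pd.DataFrame(sc_rows).to_csv(out / "scratch_counts.csv", index=False)

    gt = {
        "params": asdict(p),
        "mea_spike_times": {w: {e: list(map(float, t)) for e, t in d.items()}
                            for w, d in cohort.mea_ground_truth.items()},
        "ca_event_times": {f: {r: list(map(float, t)) for r, t in d.items()}
                           for f, d in cohort.ca_ground_truth.items()},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)
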