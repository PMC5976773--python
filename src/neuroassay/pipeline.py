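"""End-to-end orchestration: simulate -> detect -> summarize -> test.

Everything is deterministic given (config, seed); every output table
carries the config hash so numbers in the report are traceable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List

import pandas as pd

from . import __version__
from .calcium import (active_cell_filter, background_subtract,
                      call_relevant_peaks, event_frequency)
from .config import RunConfig, config_hash
from .mea import (FilterSpec, ThresholdSpec, bandpass_filter, detect_spikes,
                  well_spike_rate)
from .scratch import reinvasion_timecourse
from .stats import anova_tukey, group_summary, rm_anova
from .synth import SynthParams, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["params_from_config", "run_pipeline", "validate_inputs"]


def params_from_config(cfg: RunConfig) -> SynthParams:
    return SynthParams(seed=cfg.seed, **cfg.sim.model_dump())


def _mea_table(cfg: RunConfig, cohort) -> pd.DataFrame:
    fspec = FilterSpec(**cfg.mea.filter.model_dump())
    tspec = ThresholdSpec(**cfg.mea.threshold.model_dump())
    rows = []
    design = cohort.design.set_index("well_or_cell")
    for wid, traces in cohort.mea_traces.items():
        trains = [detect_spikes(bandpass_filter(tr, fspec), tspec) for tr in traces]
        summ = well_spike_rate(trains, traces[0].duration_s,
                               cfg.mea.active_rate_min_per_min)
        meta = design.loc[wid]
        rows.append({"well": wid, "line": meta["line"], "group": meta["group"],
                     "replicate": meta["replicate"],
                     "well_mean_rate_hz": summ.well_mean_rate_hz,
                     "active_mean_rate_hz": summ.active_mean_rate_hz,
                     "active_electrodes": summ.active_electrode_count})
    return pd.DataFrame(rows)


def _calcium_table(cfg: RunConfig, cohort) -> pd.DataFrame:
    rows = []
    design = cohort.design.set_index("well_or_cell")
    # simulator traces model already-background-subtracted fluorescence with
    # the resting F0 retained; only the configured background is removed
    bg = cfg.ca.background if not isinstance(cfg.ca.background, str) else 0.0
    for fid, traces in cohort.calcium.items():
        meta = design.loc[fid]
        results = []
        for raw in traces:
            tr = background_subtract(raw, bg)
            calls = call_relevant_peaks(tr, rule=cfg.ca.rule,
                                        sd_multiplier=cfg.ca.sd_multiplier,
                                        area=cfg.ca.area)
            results.append(event_frequency(calls, tr.duration_s, roi_id=tr.roi_id))
        active = active_cell_filter(results)
        for r in active:
            rows.append({"field": fid, "roi": r.roi_id, "line": meta["line"],
                         "group": meta["group"], "replicate": meta["replicate"],
                         "n_events": r.n_relevant_events,
                         "freq_per_min": r.frequency_per_min})
    return pd.DataFrame(rows)


def _scratch_table(cohort) -> pd.DataFrame:
    design = cohort.design.set_index("well_or_cell")
    frames = []
    for sid, series in cohort.scratch.items():
        tc = reinvasion_timecourse(series)
        meta = design.loc[sid]
        tc["line"] = meta["line"]
        tc["replicate"] = meta["replicate"]
        frames.append(tc)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: RunConfig, out_dir, force: bool = False) -> Dict:
    """Run the full synthetic-cohort pipeline and write the cohort report.

    Returns the report dict; all intermediate tables are written under
    ``out_dir`` and stamped with the config hash.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output path {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)

    params = params_from_config(cfg)
    cohort = simulate_cohort(params, render_voltage=True)

    mea_df = _mea_table(cfg, cohort)
    ca_df = _calcium_table(cfg, cohort)
    sc_df = _scratch_table(cohort)
    for name, df in (("mea_well_rates", mea_df), ("calcium_cells", ca_df),
                     ("scratch_timecourse", sc_df)):
        df = df.copy()
        df["config_hash"] = chash
        df.to_csv(out / f"{name}.csv", index=False)

    report: Dict = {"config_hash": chash, "seed": cfg.seed,
                    "software_version": __version__, "assays": {}}

    mea_an = anova_tukey(mea_df["well_mean_rate_hz"], mea_df["group"])
    report["assays"]["mea"] = {
        "summary": group_summary(mea_df["well_mean_rate_hz"], mea_df["group"]).groups,
        "anova": {"F": mea_an.F, "df": [mea_an.df_between, mea_an.df_within],
                  "p": mea_an.p},
        "tukey": [asdict(p) for p in mea_an.pairwise],
    }

    if cfg.stats.unit == "well":
        ca_unit = (ca_df.groupby(["field", "group"], as_index=False)["freq_per_min"]
                   .mean())
    else:
        ca_unit = ca_df
    ca_an = anova_tukey(ca_unit["freq_per_min"], ca_unit["group"])
    report["assays"]["calcium"] = {
        "summary": group_summary(ca_unit["freq_per_min"], ca_unit["group"]).groups,
        "anova": {"F": ca_an.F, "df": [ca_an.df_between, ca_an.df_within],
                  "p": ca_an.p},
        "tukey": [asdict(p) for p in ca_an.pairwise],
    }

    rm = rm_anova(sc_df.rename(columns={"count": "value"}), value="value",
                  subject="well", within="day", between="group")
    report["assays"]["scratch"] = {
        "rm_anova": {"group": rm.group, "time": rm.time,
                     "interaction": rm.interaction,
                     "gg_epsilon": rm.gg_epsilon,
                     "interaction_p_gg": rm.interaction_p_gg},
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("pipeline report written to %s", out / "report.json")
    return report


def validate_inputs(paths: List) -> List[Dict]:
    """Per-file validation: returns a list of {path, ok, reason} entries.

    Never raises on unreadable or malformed files and never mutates them.
    """
    findings = []
    for p in paths:
        p = Path(p)
        entry = {"path": str(p), "ok": True, "reason": ""}
        try:
            df = pd.read_csv(p)
            cols = set(df.columns)
            if p.name == "design.csv" or "group" in cols:
                bad = set(df.get("group", pd.Series(dtype=str)).unique()) - {"case", "control"}
                if bad:
                    entry.update(ok=False, reason=f"unknown group label(s): {sorted(bad)}")
            elif "time_s" in cols:
                data_cols = cols - {"time_s"}
                if not data_cols:
                    entry.update(ok=False, reason="no data columns besides time_s")
                elif df[list(data_cols)].isna().any().any():
                    entry.update(ok=False, reason="missing values in data columns")
            elif {"well", "day", "count"} <= cols:
                if (df["count"] < 0).any():
                    entry.update(ok=False, reason="negative counts")
            else:
                entry.update(ok=False, reason=f"unrecognized column set: {sorted(cols)}")
        except Exception as exc:  # unreadable file -> fail entry, not crash
            entry.update(ok=False, reason=f"unreadable: {exc}")
        findings.append(entry)
    return findings
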