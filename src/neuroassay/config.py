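"""Run configuration: schema-validated, unknown keys rejected."""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterConfig(_Strict):
    low_hz: float = Field(200.0, gt=0)
    high_hz: float = Field(2500.0, gt=0)
    order: int = Field(1, ge=1)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.low_hz < self.high_hz:
            raise ValueError("require low_hz < high_hz")
        return self


class ThresholdConfig(_Strict):
    k: float = Field(5.25, gt=0)
    window_s: float = Field(0.1, gt=0)
    dead_time_s: float = Field(1e-3, ge=0)
    polarity: Literal["negative", "positive", "both"] = "both"


class MeaConfig(_Strict):
    filter: FilterConfig = FilterConfig()
    threshold: ThresholdConfig = ThresholdConfig()
    active_rate_min_per_min: float = Field(5.0, ge=0)


class CaConfig(_Strict):
    rule: Literal["literal", "peak_population", "sd_only"] = "literal"
    area: Literal["triangle", "under_curve"] = "triangle"
    sd_multiplier: float = Field(1.0, gt=0)
    background: Union[float, str] = 0.0  # scalar or name of a background column


class ScratchRoiConfig(_Strict):
    width_mm: float = Field(1.3, gt=0)
    height_mm: float = Field(0.35, gt=0)


class ScratchConfig(_Strict):
    roi: ScratchRoiConfig = ScratchRoiConfig()


class StatsConfig(_Strict):
    unit: Literal["well", "cell"] = "well"
    alpha: float = Field(0.05, gt=0, lt=1)
    gg_correction: bool = False


class SimConfig(_Strict):
    """Synthetic cohort scale and effect sizes (see synth.SynthParams)."""

    n_case_lines: int = Field(6, ge=1)
    n_control_lines: int = Field(5, ge=1)
    wells_per_group: int = Field(16, ge=1)
    replicates: int = Field(3, ge=1)
    mea_rate_control: float = Field(2.0, gt=0)
    mea_effect: float = Field(0.5, gt=0, le=1)
    mea_duration_s: float = Field(600.0, gt=0)
    n_electrodes: int = Field(64, ge=1)
    noise_sd: float = Field(10.0, ge=0)
    spike_amplitude_sd: float = Field(8.0, gt=0)
    silent_fraction: float = Field(0.5, ge=0, le=1)
    ca_event_rate_control: float = Field(2.0, gt=0)
    ca_effect: float = Field(0.5, gt=0, le=1)
    ca_duration_s: float = Field(600.0, gt=0)
    ca_rois_per_field: int = Field(10, ge=1)
    scratch_rate_control: float = Field(30.0, gt=0)
    scratch_effect: float = Field(0.5, gt=0, le=1)
    scratch_divergence_day: int = Field(4, ge=0)
    scratch_days: int = Field(10, ge=1)


class RunConfig(_Strict):
    seed: int = 0
    sim: SimConfig = SimConfig()
    mea: MeaConfig = MeaConfig()
    ca: CaConfig = CaConfig()
    scratch: ScratchConfig = ScratchConfig()
    stats: StatsConfig = StatsConfig()


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` is merged on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = _deep_merge(data, overrides)
    return RunConfig.model_validate(data)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full (defaults included) configuration."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
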