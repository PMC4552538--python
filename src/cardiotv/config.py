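"""Validated run configuration for the pipeline.

A :class:`RunConfig` is validated up front (unknown keys rejected) and then
handed to :mod:`cardiotv.pipeline`.  It can be loaded from YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .estimator import DEFAULT_LAMBDA_GRID, DEFAULT_POLE, LAMBDA_RANGE


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    pre_s: float = 600.0
    stim_s: float = 60.0
    post_s: float = 600.0
    snr: float | None = 10.0
    #: branch -> [gain factor, end time s]: transient kernel scaling from
    #: stimulus onset until end time (e.g. {"BPC": [0.5, 60.0]})
    stimulus_gain: dict[str, tuple[float, float]] = Field(default_factory=dict)


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fs_hz: float = 2.0
    detrend_order: int = 5
    interpolation: str = "cubic"
    baseline_window_s: tuple[float, float] = (-300.0, -60.0)

    @field_validator("interpolation")
    @classmethod
    def _check_method(cls, v: str) -> str:
        if v not in ("cubic", "linear"):
            raise ValueError("interpolation must be 'cubic' or 'linear'")
        return v


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    profile: str = "fast"
    pole: float = DEFAULT_POLE
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_surrogates: int = 50
    init_scale: float = 100.0
    seed: int = 0
    models: tuple[str, ...] = ("hrv", "pr")

    @field_validator("profile")
    @classmethod
    def _check_profile(cls, v: str) -> str:
        if v not in ("fast", "full"):
            raise ValueError("profile must be 'fast' or 'full'")
        return v

    @field_validator("lambda_grid")
    @classmethod
    def _check_grid(cls, v):
        lo, hi = LAMBDA_RANGE
        for lam in v:
            if not (lo <= lam <= hi or lam == 1.0):
                raise ValueError(f"lambda {lam} outside [{lo}, {hi}]")
        return v


class DescriptorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nfft: int = 256
    ar_order: int = 8
    psd_lambda: float = 0.97
    psd_surrogates: int = 50
    compute_spectra: bool = True
    #: label -> [t_lo, t_hi] seconds relative to onset; must include 'baseline'
    bins: dict[str, tuple[float, float]] | None = None


class RunConfig(BaseModel):
    """Top-level configuration of a pipeline run."""

    model_config = ConfigDict(extra="forbid")

    outdir: str = "cardiotv_out"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    descriptors: DescriptorConfig = Field(default_factory=DescriptorConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def to_json(self) -> dict:
        return json.loads(self.model_dump_json())
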