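"""Strictly validated pipeline configuration.

The YAML config mirrors the six pipeline stages (simulate / process / screen /
infer / features / cluster) plus a global seed and output directory.  Unknown
keys are rejected, every parameter is range-checked before any stage runs,
and the defaults are the acquisition/analysis parameters of the reference
workflow: 20 FPS, 7-px ROIs, a 5-frame moving average, 25-s drift blocks, a
0.8% ΔF/F0 detection threshold with τ = 1 s, the 1-s burst rule, and k = 8
clusters.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError

__all__ = ["PipelineConfig", "validate_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Strict):
    fps: float = Field(20.0, gt=0)
    frame_height_px: int = Field(720, ge=1)
    frame_width_px: int = Field(960, ge=1)
    um_per_px: float = Field(4.40, gt=0)
    roi_size_px: int = Field(7, ge=1)
    duration_s: float = Field(600.0, gt=0)


class SimulateConfig(_Strict):
    # 200-neuron demo population: 84% active split 60/32/8 into LF/IF/HF.
    class_counts: dict[str, int] = Field(
        default_factory=lambda: {"low": 101, "intermediate": 54, "high": 13, "inactive": 32}
    )
    amplitude_pct: float = Field(2.0, gt=0)
    tau_s: float = Field(1.0, gt=0)
    baseline: float = Field(100.0, gt=0)
    noise_sd: float = Field(0.5, ge=0)
    drift_amplitude: float = Field(2.0, ge=0)
    drift_period_s: float = Field(300.0, ge=100)
    write_movie: bool = False
    movie_n_neurons: int = Field(9, ge=0)


class ProcessConfig(_Strict):
    window_frames: int = Field(5, ge=1)
    block_s: float = Field(25.0, gt=0)
    f0_percentile: float = Field(10.0, gt=0, lt=100)
    detection_threshold: float = Field(0.0, ge=0)
    min_separation_px: float = Field(7.0, ge=0)


class ScreenConfig(_Strict):
    n_rounds: int = Field(50, ge=1)
    n_labeled_per_class: int = Field(100, ge=1)
    threshold_pct: float | None = None  # None → 2× robust noise SD per trace


class InferConfig(_Strict):
    threshold_pct: float = Field(0.8, gt=0)
    tau_s: float = Field(1.0, gt=0)
    amplitude_pct: float = Field(2.0, gt=0)
    min_duration_frames: int = Field(2, ge=1)


class FeaturesConfig(_Strict):
    max_isi_s: float = Field(1.0, gt=0)


class ClusterConfig(_Strict):
    k: int = Field(8, ge=1)
    n_restarts: int = Field(50, ge=1)
    standardize: bool = True
    n_components: int | None = None  # None → all PCs


class PipelineConfig(_Strict):
    seed: int = Field(0, ge=0, lt=2**31)
    outdir: str = "capheno_out"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    process: ProcessConfig = Field(default_factory=ProcessConfig)
    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    infer: InferConfig = Field(default_factory=InferConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)


def validate_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load, default and validate a YAML config.

    ``path=None`` or an empty file yields the full default config.  Type or
    range violations raise :class:`ConfigError` naming the offending key
    path; unknown keys are rejected.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded
    if overrides:
        for key, value in overrides.items():
            if isinstance(value, dict):
                data.setdefault(key, {})
                data[key].update(value)
            else:
                data[key] = value
    try:
        return PipelineConfig(**data)
    except ValidationError as err:
        lines = [
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        ]
        raise ConfigError("invalid config — " + "; ".join(lines)) from err
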