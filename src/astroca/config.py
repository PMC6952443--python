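"""Typed, validated pipeline configuration (YAML round-trippable)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SyntheticBlock(_Strict):
    height: int = 128
    width: int = 128
    n_frames: int = 300
    frame_interval: float = 0.5
    n_somas: int = 8
    n_processes: int = 10
    n_endfeet: int = 6
    transient_rate: float = 1.5
    transient_amplitude: float = 0.5
    rise_tau: float = 1.0
    decay_tau: float = 4.0
    drift_rank: int = 3
    drift_amplitude: float = 0.1
    rigid_shift_amplitude: float = 2.0
    nonrigid_amplitude: float = 1.0
    noise_sd: float = 5.0
    noise_model: str = "gaussian"


class MotionBlock(_Strict):
    reference: int | str = "template"
    subpixel: int = 10
    clg: bool = True
    clg_lambda: float = 0.02
    clg_iterations: int = 60
    pyramid_levels: int = 3


class BaselineBlock(_Strict):
    rank: int = 20
    irls_iterations: int = 10
    irls_asymmetry: float = 0.1
    window_frames: int = 30
    window_pixels: int = 16
    floor_fraction: float = 0.01

    @field_validator("rank")
    @classmethod
    def _rank_pos(cls, v: int) -> int:
        if v < 1:
            raise ValueError("rank must be >= 1")
        return v


class DetectionBlock(_Strict):
    window_size: int = 16
    window_stride: int = 8
    n_pcs: int = 5
    n_clusters: int = 3
    smoothing_width: float = 3.0
    threshold_sd: float = 2.0

    @field_validator("threshold_sd")
    @classmethod
    def _thr_pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("threshold_sd must be > 0")
        return v

    @model_validator(mode="after")
    def _stride(self) -> "DetectionBlock":
        if self.window_stride > self.window_size:
            raise ValueError("window_stride must be <= window_size")
        return self


class SegmentationBlock(_Strict):
    block_size: int = 11
    persistence_fraction: float = 0.5
    connectivity: int = 8
    min_roi_area: int = 6
    contrast_floor: float = 5.0

    @field_validator("block_size")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v < 3 or v % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")
        return v


class EventsBlock(_Strict):
    min_duration_frames: int = 2
    responder_min_relative_increase: float = 0.2
    stimulus_onset_frame: int | None = None
    stimulus_offset_frame: int | None = None


class PhysioBlock(_Strict):
    map_window: float = 2.0
    rsna_tau: float = 0.1
    delay_k: float = 2.0
    delay_m: int = 5


class IOBlock(_Strict):
    functional_tiff: str | None = None
    structural_tiff: str | None = None
    physio_csv: str | None = None
    physio_sidecar: str | None = None
    frame_interval: float = 0.5
    output_dir: str = "astroca_out"


class PipelineConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    synthetic: SyntheticBlock | None = None
    motion: MotionBlock = MotionBlock()
    baseline: BaselineBlock = BaselineBlock()
    detection: DetectionBlock = DetectionBlock()
    segmentation: SegmentationBlock = SegmentationBlock()
    events: EventsBlock = EventsBlock()
    physio: PhysioBlock = PhysioBlock()
    io: IOBlock = IOBlock()

    @model_validator(mode="after")
    def _has_input(self) -> "PipelineConfig":
        if self.synthetic is None and self.io.functional_tiff is None:
            raise ValueError(
                "either a synthetic block or io.functional_tiff is required")
        return self


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse + validate a YAML document (or dict) into a PipelineConfig.

    An empty document yields all defaults with a synthetic input block;
    unknown keys and type errors are rejected with the offending path.
    """
    if isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if "synthetic" not in data and not data.get("io", {}).get("functional_tiff"):
        data["synthetic"] = {}
    return PipelineConfig.model_validate(data)


def load_config(path: str | Path) -> PipelineConfig:
    return validate_config(Path(path).read_text())


def dump_config(config: PipelineConfig) -> str:
    return yaml.safe_dump(config.model_dump(), sort_keys=True)
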