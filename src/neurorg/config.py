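"""Declarative run configuration (YAML) with strict schema validation."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImagingSettings(_Strict):
    pixel_size: float = 0.08          # um/px
    frame_interval: float = 5.0       # s
    n_frames: int = 97
    frame_shape: tuple[int, int] = (512, 512)


class FrangiSettings(_Strict):
    scales: list[float] = [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
    beta: float = 0.5
    gamma: float | None = None        # None -> half max Hessian norm per scale


class HysteresisSettings(_Strict):
    noise_mult: float = 8.0           # low = noise_mult * median nonzero strength


class SomaSettings(_Strict):
    dog_scales: list[float] = [10.0, 15.0, 20.0, 25.0, 30.0, 40.0]
    open_radius_px: int = 12
    soma_margin_px: int = 3
    downsample: int = 2           # decimation for the (large-scale) DoG filter


class DetectionSettings(_Strict):
    sigma_po: float = 1.0
    sigma_mito: float = 2.0
    sigma_fixed: float = 0.0      # fixed-cell blur: raw Otsu, as in the distribution workflow
    min_size: int = 4


class TrackingSettings(_Strict):
    max_link_dist: float = 1.0        # um per frame


class MotilitySettings(_Strict):
    displacement_floor: float = 0.1   # um
    min_track_fraction: float = 0.8   # cohort filter: tracks spanning >= this


class DistributionSettings(_Strict):
    proximal_length: float = 30.0     # um
    contact_dilation_px: int = 1


class RunConfig(_Strict):
    imaging: ImagingSettings = ImagingSettings()
    frangi: FrangiSettings = FrangiSettings()
    hysteresis: HysteresisSettings = HysteresisSettings()
    soma: SomaSettings = SomaSettings()
    detection: DetectionSettings = DetectionSettings()
    tracking: TrackingSettings = TrackingSettings()
    motility: MotilitySettings = MotilitySettings()
    distribution: DistributionSettings = DistributionSettings()
    input_dir: str | None = None
    group_a: list[str] | None = None
    group_b: list[str] | None = None
    output_dir: str = "neurorg-out"
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} not found")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {details}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json")))
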