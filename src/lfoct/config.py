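"""Run configuration: validated parameter blocks with instrument defaults.

Every field defaults to the as-built system value (833/40 nm source,
796-879 nm over 1920 pixels, 0.08 nm practical resolution, 850 A-scans,
0.5 ms exposure, 12-bit depth, 120 fps, 600 B-scans over a 4 mm scan).
Configs are YAML files; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, \
    field_validator

from . import system
from .forward_sim import CameraModel, SourceSpectrum, SpectrographModel

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SourceConfig(_Block):
    center_nm: float = system.SOURCE_CENTER_NM
    fwhm_nm: float = Field(system.SOURCE_FWHM_NM, gt=0)
    power_mw: float = Field(system.SOURCE_POWER_MW, gt=0)

    def build(self) -> SourceSpectrum:
        return SourceSpectrum(self.center_nm, self.fwhm_nm, self.power_mw)


class SpectrographConfig(_Block):
    n_spectral_pixels: int = Field(system.N_SPECTRAL_PIXELS, gt=0)
    n_spatial_pixels: int = Field(system.N_SPATIAL_PIXELS, gt=0)
    n_illuminated: int = Field(system.N_ILLUMINATED, gt=0)
    lambda_min_nm: float = system.LAMBDA_MIN_NM
    lambda_max_nm: float = system.LAMBDA_MAX_NM
    resolution_fwhm_nm: float = Field(system.RESOLUTION_FWHM_NM, ge=0)
    slit_transmission: float = Field(1.0, gt=0, le=1)

    def build(self) -> SpectrographModel:
        return SpectrographModel(
            self.n_spectral_pixels, self.n_spatial_pixels, self.n_illuminated,
            self.lambda_min_nm, self.lambda_max_nm, self.resolution_fwhm_nm,
            self.slit_transmission)


class CameraConfig(_Block):
    full_well_e: float = Field(system.FULL_WELL_E, gt=0)
    bit_depth: int = system.BIT_DEPTH
    read_noise_e: float = Field(system.READ_NOISE_E, ge=0)
    binning: Literal[1, 2] = 1
    exposure_ms: float = Field(system.EXPOSURE_MS, gt=0)
    frame_rate_fps: float = Field(system.FRAME_RATE_FPS, gt=0)

    @field_validator("bit_depth")
    @classmethod
    def _bits(cls, v: int) -> int:
        if v not in (8, 10, 12, 14, 16):
            raise ValueError("bit_depth must be one of 8, 10, 12, 14, 16")
        return v

    def build(self) -> CameraModel:
        return CameraModel(self.full_well_e, self.bit_depth, self.read_noise_e,
                           self.binning, self.exposure_ms, self.frame_rate_fps)


class PhantomConfig(_Block):
    preset: Literal["cornea", "pcb", "tape", "mirror"] = "cornea"
    n_bscans: int = Field(600, ge=1)
    n_ascans: int = Field(system.N_ILLUMINATED, ge=4)
    # preset-specific overrides; None means the preset default
    mirror_opd_um: float = 1000.0
    cornea_total_um: float = 743.2
    cornea_epithelium_um: float = 69.2
    cornea_curvature_radius_mm: float = 7.5
    pcb_coating_over_mask_um: float = 82.9
    pcb_coating_over_resistor_um: float = 27.2
    # None = self-leveling default (coating surface flush across the blocks)
    pcb_resistor_height_um: Optional[float] = None
    tape_n_layers: int = Field(10, ge=1)
    tape_layer_um: float = Field(60.0, gt=0)


class ReconConfig(_Block):
    zero_pad_factor: int = Field(2, ge=1)
    window: Literal["hann", "hamming", "rect"] = "hann"
    upsample: int = Field(8, ge=1)


class SegmentationConfig(_Block):
    half_width: int = Field(5, ge=1)
    k_sigma: float = Field(3.0, gt=0)
    wiener_size: int = Field(5, ge=3)
    # offset windows in unpadded depth bins (scaled by zero_pad_factor)
    alpha_epithelium: tuple[int, int] = (20, 60)
    alpha_endothelium: tuple[int, int] = (150, 450)
    alpha_pcb: tuple[int, int] = (5, 120)
    cornea_group_index: float = 1.376
    coating_group_index: float = 1.50


class MetricsConfig(_Block):
    psf_opd_um: float = 500.0
    psf_zero_pad_factor: int = Field(4, ge=1)
    rolloff_opd_um: tuple[float, ...] = (200.0, 500.0, 1000.0, 1500.0,
                                         2000.0, 2500.0, 3000.0)


class RunConfig(_Block):
    """Top-level configuration: one block per pipeline stage plus the seed."""

    source: SourceConfig = Field(default_factory=SourceConfig)
    spectrograph: SpectrographConfig = Field(default_factory=SpectrographConfig)
    camera: CameraConfig = Field(default_factory=CameraConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    recon: ReconConfig = Field(default_factory=ReconConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    seed: int = 0
    output_dir: Optional[str] = None


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; missing fields take system defaults.

    An empty (or absent) file yields the full default configuration.
    Unknown keys and invalid values raise ``ValueError`` naming the key.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ValueError(f"invalid config value at '{loc}': {first['msg']}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration, for run manifests."""
    blob = yaml.safe_dump(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
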