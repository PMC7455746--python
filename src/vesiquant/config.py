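"""Run configuration: validated, serializable, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImageSynthConfig(_Strict):
    height_px: int = 512
    width_px: int = 512
    pixel_size_um: float = 0.2
    n_vesicles: int = 10
    radius_range_um: tuple[float, float] = (2.0, 6.0)
    ring_sigma_um: float = 0.15
    membrane_peak_intensity: float = 2000.0
    reporter_enriched_fraction: float = 0.5
    reporter_lognormal_mu: float = 6.684611727667927  # ln(800)
    reporter_lognormal_sigma: float = 0.8
    reporter_background_intensity: float = 100.0
    psf_sigma_um: float = 0.1
    read_noise_sigma: float = 5.0
    shot_noise: bool = True


class TraceSynthConfig(_Strict):
    n_liposomes: int = 50
    time_start_min: float = 0.0
    time_stop_min: float = 960.0
    time_step_min: float = 15.0
    baseline: float = 100.0
    amplitude_mean: float = 400.0
    amplitude_sd: float = 150.0
    rate_mean_per_min: float = 0.05
    rate_sd_per_min: float = 0.02
    midpoint_mean_min: float = 240.0
    midpoint_sd_min: float = 90.0
    trace_noise_sigma: float = 10.0
    nonresponder_fraction: float = 0.5


class MSSynthConfig(_Strict):
    species: tuple[str, ...] = ("DOPE", "DOPG")
    true_concentrations_uM: dict[str, dict[str, float]] = {
        "reaction_1": {"DOPE": 12.0, "DOPG": 8.0}
    }
    calibration_levels_uM: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    calibration_slope_counts_per_uM: float = 1000.0
    calibration_intercept_counts: float = 50.0
    injections_per_sample: int = 2
    count_noise_cv: float = 0.05
    precursor_acyl_coa_uM: float = 100.0


class SegmentationConfig(_Strict):
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 20
    circularity_min: float = 0.85
    border_margin_px: int = 2
    refine_radius: bool = True


class ProfilingConfig(_Strict):
    n_angles: int = 63
    extent_factor: float = 1.5
    step_px: float = 0.5


class RunConfig(_Strict):
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    version_tag: str = "vesiquant-0.1"
    image: ImageSynthConfig = ImageSynthConfig()
    control_image: ImageSynthConfig = ImageSynthConfig(
        reporter_enriched_fraction=0.0
    )
    traces: TraceSynthConfig = TraceSynthConfig()
    ms: MSSynthConfig = MSSynthConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    profiling: ProfilingConfig = ProfilingConfig()


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise a validation error."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def dump_config(config: RunConfig, path) -> None:
    """Serialize a RunConfig to YAML (lossless round trip)."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
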