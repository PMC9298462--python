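"""Pipeline configuration: one validated object with all stage parameters.

Defaults follow the study protocol wherever it states a value (10 s
transmissions, 70 m detection range, 30 fixes/hour QC, 1-min interpolation,
5 m occupancy bins with 2.5 m smoothing, 0.5 alpha-shape shrink, 30-min
segments with 50% overlap, 4 principal components, 1.5% merger-score cut);
everything else is an explicit, documented choice. Unknown keys are
rejected so configuration typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_fish: int = Field(3, ge=1)
    n_days: int = Field(14, ge=1)
    home_extent: tuple[float, float] = (200.0, 50.0)
    home_center: tuple[float, float] = (0.0, 0.0)
    sleep_site: tuple[float, float] = (-80.0, -15.0)
    day_window: tuple[int, int] = (360, 1080)
    transmission_interval_s: float = Field(10.0, gt=0)
    night_dropout: float = Field(0.5, ge=0.0, le=1.0)
    mode_self_transition: float = Field(0.995, ge=0.0, lt=1.0)


class ArraySection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    spacing_m: float = Field(60.0, gt=0)
    margin_m: float = Field(10.0, ge=0)
    detection_range_m: float = Field(70.0, gt=0)
    timing_noise_sd_s: float = Field(0.001, ge=0)
    clock_offset_sd_s: float = Field(0.02, ge=0)
    clock_drift_sd: float = Field(2e-6, ge=0)
    beacon_every: int = Field(3, ge=1)


class IngestSection(BaseModel):
    """Paths for real (pre-recorded) inputs instead of simulation."""

    model_config = ConfigDict(extra="forbid")

    stations_csv: str | None = None
    beacons_csv: str | None = None
    detections_csv: str | None = None


class LocalizationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    speed_of_sound_m_s: float = Field(1500.0, gt=0)
    grid_spacing_m: float = Field(1.0, gt=0)
    grid_inflate_m: float = Field(50.0, ge=0)
    sync_window_s: float = Field(900.0, gt=0)


class PrepSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_per_hour: int = Field(30, ge=0)
    min_run_days: int = Field(2, ge=1)
    latitude: float = Field(29.55, ge=-90, le=90)
    longitude: float = Field(34.95, ge=-180, le=180)


class HomeRangeSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shrink_factor: float = Field(0.5, ge=0.0, le=1.0)
    occupancy_bin_m: float = Field(5.0, gt=0)
    occupancy_sigma_m: float = Field(2.5, ge=0)
    stability_k_days: int = Field(3, ge=1)


class FeatureSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    segment_length_min: float = Field(30.0, gt=0)
    overlap: float = Field(0.5, ge=0.0, lt=1.0)


class ClusterSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_components: int = Field(4, ge=1, le=13)
    threshold: float = Field(0.015, gt=0.0, lt=1.0)
    linkage_method: str = "ward"
    merge_pairs: list[tuple[int, int]] = Field(default_factory=list)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: str = "simulate"  # "simulate" | "ingest"
    seed: int = 0
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    array: ArraySection = Field(default_factory=ArraySection)
    ingest: IngestSection = Field(default_factory=IngestSection)
    localization: LocalizationSection = Field(default_factory=LocalizationSection)
    prep: PrepSection = Field(default_factory=PrepSection)
    homerange: HomeRangeSection = Field(default_factory=HomeRangeSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    clustering: ClusterSection = Field(default_factory=ClusterSection)

    @model_validator(mode="after")
    def _check_mode(self) -> "PipelineConfig":
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest":
            for name in ("stations_csv", "beacons_csv", "detections_csv"):
                if getattr(self.ingest, name) is None:
                    raise ValueError(f"ingest mode requires ingest.{name}")
        return self

    def parameter_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)
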