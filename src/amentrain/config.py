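"""Run configuration: a validated schema for the pipeline CLI.

Configs are JSON documents validated by pydantic before any data is
touched; ``RunConfig.model_json_schema()`` publishes the schema.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError


class BandSettings(BaseModel):
    """AM tier pass-bands in Hz."""

    stress_band: tuple[float, float] = (0.8, 2.5)
    syllable_band: tuple[float, float] = (2.5, 12.0)
    phoneme_band: tuple[float, float] = (12.0, 40.0)
    filter_order: int = 2

    @field_validator("stress_band", "syllable_band", "phoneme_band")
    @classmethod
    def _check_band(cls, v):
        lo, hi = v
        if not 0 < lo < hi:
            raise ValueError(f"band edges must satisfy 0 < lo < hi, got {v}")
        return v


class TrialSettings(BaseModel):
    """Trial structure for the tapping experiment."""

    sentence_duration: Optional[float] = None  # None -> take from the audio
    n_repetitions: int = 3
    stress_rate: float = 2.0
    clock_offset: float = 0.0  # tap-log clock minus audio clock, seconds


class SimulateSettings(BaseModel):
    """Knobs for the `simulate` mode."""

    n_control: int = 22
    n_dyslexic: int = 21
    control_offset_pi: float = 0.40   # planted phase offsets, units of pi
    dyslexic_offset_pi: float = 0.09
    participant_kappa: float = 5.0
    tap_kappa: float = 10.0
    syllable_rate: float = 4.0
    n_syllables: int = 8
    sample_rate: float = 16000.0


class RunConfig(BaseModel):
    """Top-level pipeline configuration."""

    bands: BandSettings = Field(default_factory=BandSettings)
    envelope_rate: float = 1000.0
    spectral_band: Union[Literal["broadband"], int] = "broadband"
    energy_threshold_db: float = -40.0
    rayleigh_alpha: float = 0.05
    seed: int = 0
    trial: TrialSettings = Field(default_factory=TrialSettings)
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    sentences: dict[str, str] = Field(
        default_factory=lambda: {
            "troch1": "trochaic", "troch2": "trochaic",
            "iamb1": "iambic", "iamb2": "iambic",
        }
    )
    audio_dir: Optional[str] = None
    taps_file: Optional[str] = None
    onsets_file: Optional[str] = None
    behaviour_file: Optional[str] = None
    recordings_manifest: Optional[str] = None
    metronome_rate: float = 2.0
    out_dir: str = "results"

    @field_validator("envelope_rate")
    @classmethod
    def _env_rate(cls, v):
        if v < 80:
            raise ValueError("envelope_rate must be >= 80 Hz (2x phoneme band edge)")
        return v

    @field_validator("sentences")
    @classmethod
    def _metres(cls, v):
        bad = {m for m in v.values() if m not in ("trochaic", "iambic")}
        if bad:
            raise ValueError(f"unknown metre labels: {bad}")
        return v

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        try:
            return cls.model_validate_json(path.read_text())
        except ValueError as exc:
            raise ConfigurationError(f"invalid config {path}: {exc}") from exc

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()
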