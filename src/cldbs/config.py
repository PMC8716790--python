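"""Run configuration: schema, validation, loading and saving.

A single YAML/JSON document describes an entire experiment — synthetic
patient, sensing, discriminant, detector, stimulation, and tuning sections —
sharing one global seed and one FFT update clock.  Unknown keys are
rejected, and cross-section consistency (matching update intervals) is
checked before any computation runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .detector import DetectorConfig
from .discriminant import LDConfig
from .sensing import SenseConfig
from .stimulation import StimConfig
from .synthetic import ArtifactSpec, BiomarkerSpec, SymptomDynamics

__all__ = [
    "SyntheticConfig",
    "PatientConfig",
    "TuningConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic patient recording."""

    model_config = ConfigDict(extra="forbid")

    duration: float = 600.0  # s
    dt: float = 1.0  # symptom-trace grid, s
    cutoff: float = 5.0  # pain dichotomization level
    dynamics: SymptomDynamics = Field(default_factory=SymptomDynamics)
    biomarkers: list[BiomarkerSpec] = Field(
        default_factory=lambda: [
            BiomarkerSpec(
                channel=0, band=(4.0, 8.0), power_low=1.0, power_high=10.0
            )
        ]
    )
    artifacts: list[ArtifactSpec] = Field(default_factory=list)
    fs: float = 250.0
    background_rms: float = 0.5
    background_exponent: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.duration <= 0 or self.dt <= 0 or self.fs <= 0:
            raise ValueError("duration, dt, fs must be positive")
        return self


class PatientConfig(BaseModel):
    """Wash-in / wash-out response of the modeled patient."""

    model_config = ConfigDict(extra="forbid")

    tau_in: float = 60.0  # s
    tau_out: float = 90.0  # s
    relief: float = 2.0  # score units at full amplitude


class TuningConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    percentiles: list[float] = Field(default_factory=lambda: [50.0])
    max_dwell: float = 30.0  # s, lock-detection allowance
    latency_window: int = 10  # updates
    grid: dict[str, list] = Field(default_factory=dict)
    objective_weights: dict[str, float] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Top-level experiment description (see module docstring)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out: str = "out"
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    sense: SenseConfig = Field(default_factory=SenseConfig)
    ld: LDConfig | None = None  # None: fitted from an open-loop calibration
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    stimulation: StimConfig = Field(
        default_factory=lambda: StimConfig(state_targets={0: 0.0, 1: 2.0})
    )
    patient: PatientConfig = Field(default_factory=PatientConfig)
    tuning: TuningConfig = Field(default_factory=TuningConfig)

    @model_validator(mode="after")
    def _clocks(self) -> "RunConfig":
        if abs(self.detector.update_interval - self.sense.update_interval) > 1e-12:
            raise ValueError(
                "clock mismatch: detector.update_interval "
                f"({self.detector.update_interval}) != sense.update_interval "
                f"({self.sense.update_interval})"
            )
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` with
    the offending field path for schema violations (including unknown keys
    and clock mismatches).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        raise ValueError(f"invalid config {path}: {err}") from err


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: BaseModel) -> str:
    """Stable short hash of any config model, for provenance sidecars."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
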