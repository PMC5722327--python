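"""Schema-validated pipeline configuration (YAML/JSON).

A :class:`PipelineConfig` mirrors the runtime dataclasses of each stage
and validates bounds up front, so that a misconfigured run fails with a
path to the offending key instead of deep inside a stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .cohort import GroupConfig, default_groups
from .errors import ConfigError
from .ml import ClassifierSpec, CvSpec
from .spectral import WindowSpec
from .synthetic import ExcitationSpec, NoiseSpec


class ExcitationConfig(BaseModel):
    component_freqs: List[float] = [float(f) for f in range(4, 33, 2)]
    peak_to_peak: float = Field(2.0, gt=0)
    fs: float = Field(1024.0, gt=0)
    duration: float = Field(16.0, gt=0)
    phase_seed: int = 0

    def to_runtime(self) -> ExcitationSpec:
        return ExcitationSpec(component_freqs=tuple(self.component_freqs),
                              peak_to_peak=self.peak_to_peak, fs=self.fs,
                              duration=self.duration, phase_seed=self.phase_seed)


class NoiseConfig(BaseModel):
    breathing_freq: float = Field(0.25, ge=0)
    breathing_flow_amplitude: float = Field(0.4, ge=0)
    pressure_noise_sd: float = Field(0.05, ge=0)
    flow_noise_sd: float = Field(0.02, ge=0)

    def to_runtime(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class WindowConfig(BaseModel):
    block_len: int = Field(4096, gt=0)
    overlap_fraction: float = Field(0.5, ge=0, lt=1)
    taper: str = "hann"
    detrend: str = "linear"

    def to_runtime(self) -> WindowSpec:
        return WindowSpec(**self.model_dump())


class QcConfig(BaseModel):
    coherence_min: float = Field(0.9, ge=0, le=1)


class GroupModel(BaseModel):
    label: str
    n: int = Field(gt=0)
    R: Tuple[float, float]
    slope: Tuple[float, float]
    I: Tuple[float, float]
    C: Tuple[float, float]

    def to_runtime(self) -> GroupConfig:
        return GroupConfig(label=self.label, n=self.n, R=self.R,
                           slope=self.slope, I=self.I, C=self.C)


class StatsConfig(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)


class RocConfig(BaseModel):
    positive_group: str = "AE"
    control_group: str = "control"
    features: List[str] = ["r0", "rm", "r4", "s", "xm", "fr", "cdyn", "z4"]
    ci_level: float = Field(0.95, gt=0, lt=1)


class MlConfig(BaseModel):
    classifier: str = "parzen"
    search: str = "exhaustive"  # "exhaustive" | "none"
    positive_group: str = "AE"
    control_group: str = "control"
    features: List[str] = ["r0", "rm", "r4", "s", "xm", "fr", "cdyn", "z4"]
    cv_scheme: str = "kfold"
    k: int = Field(10, ge=2)
    stratified: bool = True

    @field_validator("search")
    @classmethod
    def _search(cls, v: str) -> str:
        if v not in ("exhaustive", "none"):
            raise ValueError("search must be 'exhaustive' or 'none'")
        return v

    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(name=self.classifier)

    def cv_spec(self, seed: int) -> CvSpec:
        return CvSpec(scheme=self.cv_scheme, k=self.k,
                      stratified=self.stratified, seed=seed)


class IoConfig(BaseModel):
    write_records: bool = False  # raw 16 s records are bulky; off by default


class PipelineConfig(BaseModel):
    """Full configuration of the simulate -> estimate -> extract ->
    stats/roc/ml chain.  All randomness derives from ``seed``."""

    schema_version: int = 1
    seed: int = 0
    n_exams: int = Field(3, ge=1)
    groups: Optional[List[GroupModel]] = None
    excitation: ExcitationConfig = ExcitationConfig()
    noise: NoiseConfig = NoiseConfig()
    window: WindowConfig = WindowConfig()
    qc: QcConfig = QcConfig()
    stats: StatsConfig = StatsConfig()
    roc: RocConfig = RocConfig()
    ml: MlConfig = MlConfig()
    io: IoConfig = IoConfig()

    def group_configs(self) -> List[GroupConfig]:
        if self.groups is None:
            return default_groups()
        return [g.to_runtime() for g in self.groups]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def validate_config(raw: Dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "->".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {locs}") from exc


def default_config() -> PipelineConfig:
    return PipelineConfig()
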