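"""Pipeline configuration: one YAML file validating into typed sub-configs.

Every length-bearing key names its unit (``_nm``, ``_um``); the global seed
feeds every random stage, so one config + one seed reproduces a run
bit-identically for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError
from .imaging import AcquisitionSettings
from .morphometry import ClassificationRule
from .scene import NucleoidPlacement, SceneParams
from .segmentation import SegmentationConfig
from .spatial import StatsConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    try:
        return cls(**kwargs)
    except Exception as exc:
        raise ConfigurationError(f"{cls.__name__}: {exc}") from exc


@dataclass
class PipelineConfig:
    scene: SceneParams = field(default_factory=SceneParams)
    nucleoids: NucleoidPlacement = field(default_factory=NucleoidPlacement)
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    confocal: AcquisitionSettings = field(
        default_factory=lambda: AcquisitionSettings(I_dep_mW=0.0)
    )
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    rule: ClassificationRule = field(default_factory=ClassificationRule)
    stats: StatsConfig = field(default_factory=StatsConfig)
    Is_mW: float = 0.864
    seed: int = 0
    output_dir: str = "mitograph_out"

    def validate(self) -> None:
        self.scene.validate()
        self.nucleoids.validate()
        self.acquisition.validate()
        self.confocal.validate()
        self.segmentation.validate()
        self.stats.validate()
        if self.Is_mW <= 0:
            raise ConfigurationError("Is_mW must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sub = {
            "scene": SceneParams,
            "nucleoids": NucleoidPlacement,
            "acquisition": AcquisitionSettings,
            "confocal": AcquisitionSettings,
            "segmentation": SegmentationConfig,
            "rule": ClassificationRule,
            "stats": StatsConfig,
        }
        kwargs = {}
        for key, cls in sub.items():
            if key in data:
                kwargs[key] = _build(cls, data.pop(key) or {})
        known = {"Is_mW", "seed", "output_dir"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown top-level keys {sorted(unknown)}")
        kwargs.update(data)
        cfg = PipelineConfig(**kwargs)
        cfg.validate()
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the canonical JSON form of a config."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
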