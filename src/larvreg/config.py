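"""YAML-backed configuration for the registration pipelines.

One file covers every stage::

    global:
      levels: 4
      max_samples: 8000
    deformable:
      grid_spacing: 12.0
      levels: 5
      metric: masked_local_NCC
      subregion_edge: 20.0
      iterations_per_level: 300
      samples_per_iteration: 2048
      seed: 0
    correction:
      relative_weight: 1.0
    qa:
      threshold: 50.0
    template:
      fusion: median
      include_identity: true
      linear_levels: 3
      s_cap: 10.0
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .deformable import DeformableConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class GlobalConfig:
    levels: int = 4
    max_samples: int = 8000


@dataclass
class CorrectionConfig:
    relative_weight: float = 1.0


@dataclass
class QAConfig:
    threshold: float = 50.0


@dataclass
class TemplateConfig:
    fusion: str = "median"
    include_identity: bool = True
    linear_levels: int = 3
    s_cap: float = 500.0


@dataclass
class PipelineConfig:
    global_: GlobalConfig = field(default_factory=GlobalConfig)
    deformable: DeformableConfig = field(
        default_factory=lambda: DeformableConfig(metric="masked_local_NCC")
    )
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    qa: QAConfig = field(default_factory=QAConfig)
    template: TemplateConfig = field(default_factory=TemplateConfig)

    def to_dict(self) -> dict:
        return {
            "global": dataclasses.asdict(self.global_),
            "deformable": dataclasses.asdict(self.deformable),
            "correction": dataclasses.asdict(self.correction),
            "qa": dataclasses.asdict(self.qa),
            "template": dataclasses.asdict(self.template),
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _merge(cls, values: Optional[dict]):
    return cls(**(values or {}))


def load_config(path=None) -> PipelineConfig:
    """Defaults, overridden section-by-section from a YAML file if given."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        global_=_merge(GlobalConfig, raw.get("global")),
        deformable=_merge(DeformableConfig, raw.get("deformable")),
        correction=_merge(CorrectionConfig, raw.get("correction")),
        qa=_merge(QAConfig, raw.get("qa")),
        template=_merge(TemplateConfig, raw.get("template")),
    )
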