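"""Pipeline configuration: one YAML document driving every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .modeling import ModelSpec
from .preprocessing import FilterSpec
from .segmentation import SegmentationParams
from .simulate import CohortSpec


@dataclass
class PipelineConfig:
    cohort: Dict[str, object] = field(default_factory=dict)
    filter: Dict[str, object] = field(default_factory=dict)
    segmentation: Dict[str, object] = field(default_factory=dict)
    model: Dict[str, object] = field(default_factory=dict)
    search: Dict[str, object] = field(default_factory=dict)
    out_dir: str = "out"
    seed: int = 0

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        return CohortSpec(**kwargs)

    def filter_spec(self, fs_hz: float) -> FilterSpec:
        return FilterSpec(fs_hz=fs_hz, **self.filter)

    def segmentation_params(self) -> SegmentationParams:
        kwargs = dict(self.segmentation)
        if "to_window_s" in kwargs:
            kwargs["to_window_s"] = tuple(kwargs["to_window_s"])
        return SegmentationParams(**kwargs)

    def model_spec(self) -> ModelSpec:
        kwargs = dict(self.model)
        kwargs.setdefault("seed", self.seed)
        return ModelSpec(**kwargs)

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Dict[str, object]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
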