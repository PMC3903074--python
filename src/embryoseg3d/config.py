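"""Pipeline configuration: one serializable object covering every stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import ErrorTolerances
from .filtering import FilterParams
from .io import VoxelSpacing
from .preprocess import PreprocessParams
from .segment2d import GrowthParams
from .temporal import DissimilarityParams


@dataclass
class PipelineConfig:
    """All tunables of the five-stage pipeline, YAML round-trippable."""

    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(0.09, 0.09, 0.71))
    time_step_s: float = 90.0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segment: GrowthParams = field(default_factory=GrowthParams)
    center_rule: str = "sign_corrected"
    predict: DissimilarityParams = field(default_factory=DissimilarityParams)
    filter: FilterParams = field(default_factory=FilterParams)
    evaluate: ErrorTolerances = field(default_factory=ErrorTolerances)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict = {}
        if "spacing" in data:
            kwargs["spacing"] = VoxelSpacing(**data.pop("spacing"))
        for key, typ in [
            ("preprocess", PreprocessParams),
            ("segment", GrowthParams),
            ("predict", DissimilarityParams),
            ("filter", FilterParams),
            ("evaluate", ErrorTolerances),
        ]:
            if key in data:
                kwargs[key] = typ(**data.pop(key))
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
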