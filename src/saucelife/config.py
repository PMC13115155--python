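"""Pipeline configuration: one YAML file drives every subcommand."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imgen import StudySpec, default_study_spec
from .io import segmentation_params_from_dict, spec_to_dict, study_spec_from_dict
from .segment import SegmentationParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML.

    Defaults match the module-level defaults: the 36-sample
    two-temperature study, the standard segmentation thresholds, 1000
    bootstrap resamples, and acceptability-limit analysis at 90, 150 and
    180 days with the probability curve examined at 120 days.
    """

    output_dir: str = "results/pipeline"
    study: StudySpec = field(default_factory=default_study_spec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    use_abs_correlation: bool = False
    n_boot: int = 1000
    seed: int = 42
    fixed_times: tuple[float, ...] = (90.0, 150.0, 180.0)
    curve_time: float = 120.0
    ccc_weights: tuple[float, float, float] = (0.68, 0.25, 0.25)

    def validate(self) -> None:
        self.study.validate()
        self.segmentation.validate()
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if any(t < 0 for t in self.fixed_times):
            raise ValueError("fixed_times must be >= 0 days")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study"] = spec_to_dict(self.study)
        d["segmentation"] = spec_to_dict(self.segmentation)
        d["fixed_times"] = list(self.fixed_times)
        d["ccc_weights"] = list(self.ccc_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "study" in d:
            d["study"] = study_spec_from_dict(d["study"])
        if "segmentation" in d:
            d["segmentation"] = segmentation_params_from_dict(d["segmentation"])
        if "fixed_times" in d:
            d["fixed_times"] = tuple(d["fixed_times"])
        if "ccc_weights" in d:
            d["ccc_weights"] = tuple(d["ccc_weights"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
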