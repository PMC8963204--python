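"""Run configuration and provenance manifest.

A pipeline run is fully described by one YAML config; unknown keys are
rejected so typos cannot silently change an analysis.  Every run writes
its effective config and a manifest (config hash, package version, file
lists, timestamp) next to its outputs; re-running with the same config
and seed reproduces identical result CSVs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    preset: str = "ND"
    donors: int = 3
    shape: tuple[int, int] = (1024, 1024)
    islets_per_donor: int | None = None
    seed: int = 0


class ThresholdConfig(_Strict):
    method: str = "otsu"  # otsu | quantile | fixed
    params: dict = Field(default_factory=dict)


class SegmentationConfig(_Strict):
    min_islet_area: int | None = None  # default: three cell footprints
    closing_radius: int = 3
    reference_channel: str = "CHGA"


class ClassifierConfig(_Strict):
    ins_min_frac: float = 0.01
    mda5_min_frac: float = 0.01
    chga_min_frac: float = 0.5
    hormone_max_frac: float = 0.01
    min_cluster_cells: int = 5
    cell_area_px: float | None = None  # default: the generator's default cell footprint


class StatisticsConfig(_Strict):
    alpha: float = 0.05
    adjust: str = "holm"  # holm | bonferroni
    exact_below: int = 8


class PipelineConfig(_Strict):
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    statistics: StatisticsConfig = Field(default_factory=StatisticsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))
        return path

    def hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


class RunManifest(_Strict):
    config_hash: str
    version: str = __version__
    inputs: list[str] = Field(default_factory=list)
    outputs: list[str] = Field(default_factory=list)
    timestamp: str = ""

    @classmethod
    def create(cls, config: PipelineConfig, inputs: list[str | Path],
               outputs: list[str | Path]) -> "RunManifest":
        return cls(
            config_hash=config.hash(),
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True))
        return path
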