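"""Pipeline configuration: YAML-backed, strictly validated.

Every stage's tunables live here with their defaults; unknown keys are
rejected so a typo can never silently fall back to a default.  Every source
of randomness takes an explicit seed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSettings(_Strict):
    n_states: int = 3
    n_genes: int = 300
    depth: int = 1
    span: float = 1.5  # root branches at day 1.5, mid-timecourse
    time_grid: list[float] = Field(default=[0.0, 0.75, 1.5, 2.25, 3.0])
    cells_per_timepoint: int = 500
    count_depth: int = 2000
    dispersion: float = 0.15
    n_batches: int = 2
    batch_magnitude: float = 0.0
    seed: int = 0


class PreprocessSettings(_Strict):
    min_total_counts: int = 0
    max_mito_fraction: float = 1.0
    pseudocount: float = 1.0
    trend_span: float = 0.05
    fdr: float = 0.05
    min_mean: float = 1e-3
    blacklist: list[str] = Field(default_factory=list)
    n_components: int = 50
    k_mnn: int = 20


class TransportSettings(_Strict):
    epsilon: float = 0.05
    lambda_source: float = 1.0
    lambda_target: float = 50.0
    max_iterations: int = 5000
    tolerance: float = 1e-8
    growth_iterations: int = 3
    collapse: dict[float, float] = Field(default_factory=dict)


class FateSettings(_Strict):
    targets: dict[str, list[str]] | None = None  # None: one set per true terminal state
    reference_time: float | None = None
    fate_subset: list[str] | None = None
    threshold: float = 0.0
    clip: float = 1e-12


class MarkersSettings(_Strict):
    enabled: bool = False
    mode: str = "ovr"  # "ovr" | "pairwise"
    label_column: str = "state_label"
    min_frac: float = 0.25
    min_lfc: float = 0.25


class PipelineConfig(_Strict):
    output_dir: str = "fatecourse_run"
    dataset_path: str | None = None  # None: simulate
    seed: int = 0
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    transport: TransportSettings = Field(default_factory=TransportSettings)
    fate: FateSettings = Field(default_factory=FateSettings)
    markers: MarkersSettings = Field(default_factory=MarkersSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
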