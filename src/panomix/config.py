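"""Run configuration: a YAML file validated against a published schema.

Seeds live only in the configuration (overridable on the command line);
no stage draws from hidden global randomness.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config", "write_schema"]


class DatasetEntry(BaseModel):
    path: str
    name: str


class SimSection(BaseModel):
    n: int = 100
    group_proportions: list[float] = [0.5, 0.5]
    group_names: list[str] = ["control", "case"]
    p: list[int] = [200, 200]
    q: list[int] = [10, 10]
    delta: float = 1.0
    noise: str = "gaussian"
    nb_dispersion: float = 0.2
    batch_shift: float = 0.0


class PCASection(BaseModel):
    k: int = Field(5, ge=1, le=5)
    scale: bool = False
    apply_fdr: bool = True


class DESection(BaseModel):
    method: str = "auto"  # auto | ols | moderated | voom
    contrast: list[str] | None = None  # [level_a, level_b]; default vs reference
    fdr: float = Field(0.05, gt=0, lt=1)

    @field_validator("method")
    @classmethod
    def _check_method(cls, v: str) -> str:
        if v not in ("auto", "ols", "moderated", "voom"):
            raise ValueError(f"unknown DE method {v!r}")
        return v


class ORASection(BaseModel):
    fdr: float = Field(0.05, gt=0, lt=1)
    collections: dict[str, str] = {}  # collection name -> GMT path
    pert_up: str | None = None
    pert_down: str | None = None


class CVSection(BaseModel):
    folds: int = Field(5, ge=2)
    repeats: int = Field(5, ge=1)
    metric: str = "auc"
    family: str = "gaussian_on_indicator"


class GridSection(BaseModel):
    alphas: list[float] = [round(0.1 * i, 1) for i in range(11)]
    lambdas: list[float] | str = "auto"
    n_auto_lambdas: int = 50
    lambda_min_ratio: float = 1e-3


class BiomarkerSection(BaseModel):
    cv: CVSection = CVSection()
    grid: GridSection = GridSection()
    level: str | None = None  # comparison level vs reference
    r_cutoff: float = Field(0.75, gt=0, le=1)
    network_fdr: float = Field(0.05, gt=0, lt=1)


class RunConfig(BaseModel):
    """Top-level run configuration (see docs for the published schema)."""

    # input: either a saved study directory, or metadata + dataset paths,
    # or a simulate section (the `simulate` stage then provides the study)
    study_dir: str | None = None
    metadata: str | None = None
    datasets: list[DatasetEntry] = []
    response: str | None = None
    reference_level: str | None = None
    simulate: SimSection | None = None

    pca: PCASection = PCASection()
    de: DESection = DESection()
    ora: ORASection = ORASection()
    biomarker: BiomarkerSection = BiomarkerSection()

    out_dir: str = "panomix_out"
    seed: int = 0

    def source_description(self) -> str:
        if self.study_dir:
            return f"study_dir:{self.study_dir}"
        if self.metadata:
            return f"files:{self.metadata}"
        if self.simulate is not None:
            return "simulated"
        return "unspecified"


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def write_schema(path: str | Path) -> None:
    """Publish the JSON schema of the configuration format."""
    Path(path).write_text(json.dumps(RunConfig.model_json_schema(), indent=2))
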