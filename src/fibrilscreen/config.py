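"""Pipeline configuration: defaults, validation, file/flag precedence."""

from __future__ import annotations

import os

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .exemplar import ExemplarParams


class SiteConfig(BaseModel):
    site_label: str = "Site2"
    residues: list[int] = Field(default_factory=lambda: list(range(38, 47)))
    anchor: int = 44
    chains: list[str] = Field(default_factory=list)  # empty → central strand
    numbering: str = "author"

    @model_validator(mode="after")
    def _anchor_in_residues(self):
        if self.anchor not in self.residues:
            raise ValueError("site.anchor must be one of site.residues")
        return self


class ExemplarConfig(BaseModel):
    spacing: float = 0.75
    margin: float = 3.5
    probe_radius: float = 1.4
    d_hb_min: float = 2.5
    d_hb_max: float = 3.5
    angle_tol_deg: float = 45.0
    d_phob: float = 4.5
    d_polar_excl: float = 3.5
    n_apolar: int = 3
    min_separation: float = 1.5
    max_pocket_radius: float = 12.0

    def to_params(self) -> ExemplarParams:
        return ExemplarParams(**self.model_dump())


class ScreenConfig(BaseModel):
    top_n: int = 50
    seed: int = 7
    n_starts: int = 6
    lead_like_filter: bool = False

    @field_validator("top_n")
    @classmethod
    def _top_n_positive(cls, v):
        if v < 1:
            raise ValueError("top_n must be >= 1")
        return v


class SarConfig(BaseModel):
    reference_compound: str = "52"
    site: str = "Site2"
    temperature: float = 310.15
    scale: float = 2.94
    include_reference: bool = True
    censored_policy: str = "exclude"


class SyntheticConfig(BaseModel):
    seed: int = 11
    n_strands: int = 5
    n_residues: int = 9
    planted: list[str] = Field(
        default_factory=lambda: ["donor", "acceptor", "hydrophobe", "acceptor", "donor"]
    )
    n_decoys: int = 30
    noise_cv: float = 0.05
    n_replicates: int = 3


class PipelineConfig(BaseModel):
    synthetic: bool = True
    structure_path: str | None = None
    library_path: str | None = None
    assay_path: str | None = None
    scores_path: str | None = None
    output_dir: str = "fibrilscreen_out"
    site: SiteConfig = Field(default_factory=SiteConfig)
    exemplar: ExemplarConfig = Field(default_factory=ExemplarConfig)
    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    sar: SarConfig = Field(default_factory=SarConfig)
    synthetic_params: SyntheticConfig = Field(default_factory=SyntheticConfig)

    @model_validator(mode="after")
    def _paths_exist(self):
        if not self.synthetic:
            for name in ("structure_path", "library_path", "assay_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"{name} is required when synthetic=false")
                if not os.path.exists(path):
                    raise ValueError(f"{name}: no such file {path!r}")
        return self


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse YAML/dict config text, fill defaults, enforce constraints."""
    if raw is None or raw == "":
        data: dict = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    return PipelineConfig.model_validate(data)
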