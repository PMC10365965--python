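"""Pipeline configuration: a single JSON document with per-stage sections.

Every published threshold (MAPQ 20, 20-bp flanks, 20-read depth floor,
VAF 0.2, population AF 0.01, nucleus/cell ratio 0.8, diameter 15 um,
half-integer count cutoffs) surfaces here with its default, validated by a
pydantic schema before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .errors import InputValidationError


class FilterSection(BaseModel):
    min_mapq: int = Field(default=20, ge=0)
    flank_len: int = Field(default=20, ge=0)
    min_depth: int = Field(default=20, ge=0)
    min_vaf: float = Field(default=0.2, ge=0.0, le=1.0)
    max_pop_af: float = Field(default=0.01, ge=0.0, le=1.0)
    loh_vaf: float = Field(default=0.95, ge=0.0, le=1.0)
    depth_basis: str = "total"

    @field_validator("depth_basis")
    @classmethod
    def _basis(cls, v: str) -> str:
        if v not in ("total", "alt"):
            raise ValueError("depth_basis must be 'total' or 'alt'")
        return v


class QcSection(BaseModel):
    min_fraction_20x: float | None = Field(default=0.3, ge=0.0, le=1.0)
    min_mean_depth: float | None = Field(default=None, ge=0.0)


class DiagnosticsSection(BaseModel):
    #: chi-squared continuity correction (off matches common software defaults)
    continuity_correction: bool = False


class SimulateSection(BaseModel):
    n_malignant: int = Field(default=97, ge=1)
    n_benign: int = Field(default=25, ge=1)
    designed_cutoff: float = Field(default=2.5, ge=0.0)
    deterministic_counts: bool = True
    n_above_malignant: int = Field(default=51, ge=0)
    n_above_benign: int = Field(default=5, ge=0)
    n_tumour_cells: int = Field(default=5, ge=0)
    n_background_cells: int = Field(default=20, ge=0)
    depth_per_site: int = Field(default=30, ge=1)
    read_len: int = Field(default=100, gt=41)


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "ctcdx_out"
    log_level: str = "INFO"
    filter: FilterSection = FilterSection()
    qc: QcSection = QcSection()
    diagnostics: DiagnosticsSection = DiagnosticsSection()
    simulate: SimulateSection = SimulateSection()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputValidationError(f"no such config file: {path}")
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise InputValidationError(f"{path}: invalid JSON: {exc}") from exc
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        payload = self.model_dump(exclude={"out_dir", "log_level"})
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def filter_config(self):
        from .variant_filtering import FilterConfig

        return FilterConfig(**self.filter.model_dump())
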