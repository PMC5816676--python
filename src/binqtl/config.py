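"""Strict YAML pipeline configuration.

The config file has one block per stage (``sim``, ``qc``, ``scan``,
``finemap``) plus a master ``seed``; unknown keys anywhere are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .binmap import QCConfig
from .qtl import ScanConfig
from .sim import QTLEffect, SimPhenotypeSpec

__all__ = ["PipelineConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QTLBlock(_Strict):
    chrom: str
    pos_bp: float
    add: float
    dom: float = 0.0


class SimBlock(_Strict):
    n_snps: int = 2000
    chrom_lengths: dict[str, int] = Field(
        default_factory=lambda: {"chr1": 150_000_000, "chr2": 150_000_000}
    )
    cm_per_mb: float = 1.0
    n_lines: int = 200
    n_selfing_generations: int = 6
    mean_depth: float = 0.1
    error_rate: float = 0.01
    qtls: list[QTLBlock] = Field(default_factory=list)
    var_line_poly: float = 0.0
    var_line_loc: float = 0.0
    var_line_year: float = 0.0
    var_residual: float = 1.0
    n_locations: int = 2
    n_years: int = 2
    n_reps: int = 2
    intercept: float = 0.0

    @field_validator("n_snps", "n_lines")
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    def phenotype_spec(self) -> SimPhenotypeSpec:
        return SimPhenotypeSpec(
            qtls=[QTLEffect(q.chrom, q.pos_bp, q.add, q.dom) for q in self.qtls],
            var_line_poly=self.var_line_poly,
            var_line_loc=self.var_line_loc,
            var_line_year=self.var_line_year,
            var_residual=self.var_residual,
            n_locations=self.n_locations,
            n_years=self.n_years,
            n_reps=self.n_reps,
            intercept=self.intercept,
        )


class QCBlock(_Strict):
    window_size: int = 20
    step: int = 2
    purity: float = 0.7
    min_window_informative: int = 5
    min_genotyped: int = 20_000
    max_line_het: float = 0.10
    max_line_breakpoints: int = 200
    max_bin_distortion: float = 2.0
    max_bin_het: float = 0.10
    emission_error: float = 0.005
    min_pair_lines: int = 20

    def qc_config(self) -> QCConfig:
        return QCConfig(**self.model_dump())


class ScanBlock(_Strict):
    n_permutations: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    n_cofactors: int = 5
    window_cm: float = 10.0
    location: str | None = None
    year: str | None = None

    def scan_config(self, seed: int) -> ScanConfig:
        return ScanConfig(
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            lod_drop=self.lod_drop,
            n_cofactors=self.n_cofactors,
            window_cm=self.window_cm,
            seed=seed,
        )


class FineMapBlock(_Strict):
    alpha: float = 0.05
    n_recombinants: int = 11
    n_progeny_per_class: int = 25
    effect: float = 3.0
    sd: float = 1.0
    region_halfwidth_bp: int = 300_000


class PipelineConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    sim: SimBlock = Field(default_factory=SimBlock)
    qc: QCBlock = Field(default_factory=QCBlock)
    scan: ScanBlock = Field(default_factory=ScanBlock)
    finemap: FineMapBlock | None = None


def load_config(path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration (for artifact stamping)."""
    canon = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
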