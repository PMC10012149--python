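"""Validated pipeline configuration (JSON, strict schema, full defaults)."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .core import SpecificationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSettings(_Strict):
    n_participants: int = 24
    class_sizes: tuple[int, int] = (12, 12)
    subset_size: int = 20
    subset_split: tuple[int, int] = (10, 10)
    n_features: int = 300
    n_responsive: int = 40
    n_discriminative: int = 10
    dose_amplitudes: tuple[float, float, float] = (0.1, 0.4, 0.8)
    class_effect_size: float = 1.0
    noise_sd: float = 0.15
    random_intercept_sd: float = 0.25
    missing_rate: float = 0.006
    n_qc: int = 10
    n_batches: int = 2
    qc_drift: float = 0.002
    qc_noise_sd: float = 0.02


class PreprocessSettings(_Strict):
    knn_k: int = 5
    qc_cv_limit: float = 0.30
    shapiro_alpha: float = 0.05
    loess_span: float = 0.75
    scaling_mode: str = "unit_variance"

    @field_validator("qc_cv_limit", "shapiro_alpha")
    @classmethod
    def _frac(cls, v, info):
        if not (0 < v < 1):
            raise ValueError(f"{info.field_name} must lie in (0, 1)")
        return v


class ScreenSettings(_Strict):
    n_permutations: int = 10_000
    q_threshold: float = 0.05

    @field_validator("q_threshold")
    @classmethod
    def _thr(cls, v):
        if not (0 < v < 1):
            raise ValueError("q_threshold must lie in (0, 1)")
        return v

    @field_validator("n_permutations")
    @classmethod
    def _nperm(cls, v):
        if v < 1:
            raise ValueError("n_permutations must be >= 1")
        return v


class GateSettings(_Strict):
    height_fraction: float = 0.75
    min_adjacent_points: int = 3
    fc_threshold: float = 1.0

    @field_validator("height_fraction")
    @classmethod
    def _hf(cls, v):
        if not (0 < v < 1):
            raise ValueError("height_fraction must lie in (0, 1)")
        return v


class RankSettings(_Strict):
    class_column: str = "ethnicity"
    n_outer_folds: int = 10
    halving_floor: int = 50
    linear_cost: float = 1.0
    cost_exponents: list[float] = Field(default_factory=lambda: [-5, -2.143, 0.714, 3.571, 6.429, 9.286, 12.143, 15])
    gamma_exponents: list[float] = Field(default_factory=lambda: [-15, -12.429, -9.857, -7.286, -4.714, -2.143, 0.429, 3])
    n_inner_folds: int = 10
    error_threshold: float = 0.05
    n_values: list[int] | None = None
    response_mode: str = "hp_minus_wc"


class ValidateSettings(_Strict):
    n_components: int = 2
    k_folds: int = 7
    n_permutations: int = 100
    top_n: int | None = None


class EnrichSettings(_Strict):
    min_degree: int = 10
    min_bc: float = 0.1
    comparison: str = "inclusive"
    adjust: str = "holm_bonferroni"
    n_pathways: int = 80
    mapped_fraction: float = 0.8
    top_n: int = 20


class PipelineConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    features_csv: str | None = None
    metadata_csv: str | None = None
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    screen: ScreenSettings = Field(default_factory=ScreenSettings)
    gate: GateSettings = Field(default_factory=GateSettings)
    rank: RankSettings = Field(default_factory=RankSettings)
    multivariate: ValidateSettings = Field(default_factory=ValidateSettings)
    enrich: EnrichSettings = Field(default_factory=EnrichSettings)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a JSON config file; empty file means all defaults, unknown keys
    and invariant violations raise a descriptive :class:`SpecificationError`."""
    text = Path(path).read_text().strip()
    payload = json.loads(text) if text else {}
    try:
        return PipelineConfig.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError carries the key names
        raise SpecificationError(str(exc)) from exc
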