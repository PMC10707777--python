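"""Pipeline configuration: a validated, JSON-serializable run description."""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator


class SmoothingSettings(BaseModel):
    lambda_grid_min: float = 1e-4
    lambda_grid_max: float = 1e3
    lambda_grid_size: int = 30
    fixed_lambda: float | None = None     # bypass GCV when set

    @model_validator(mode="after")
    def _check(self):
        if self.lambda_grid_min <= 0 or self.lambda_grid_max < self.lambda_grid_min:
            raise ValueError("invalid lambda grid")
        return self


class ClusterSettings(BaseModel):
    k_min: int = 2
    k_max: int = 6
    scree_threshold: float = 0.2
    tol: float = 1e-6
    max_iter: int = 200
    n_init: int = 25

    @model_validator(mode="after")
    def _check(self):
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("invalid K range")
        return self


class ImputationSettings(BaseModel):
    n_iter: int = 50
    k_donors: int = 5


class GeneratorSettings(BaseModel):
    n: int = 173


class RegressionSettings(BaseModel):
    n_boot: int = Field(999, description="pairs-bootstrap replicates for median CIs")
    outcomes: list[str] = Field(default_factory=lambda: [
        "hypertension", "dyslipidemia", "diabetes_bin",
        "HDL", "TG", "HOMA",
        "SCL90_GSI", "SF36_PH", "SF36_MH", "YFAS", "EAT26", "BIS11", "BES"])


class PipelineConfig(BaseModel):
    """Everything a reproducible end-to-end run needs besides the seed."""

    seed: int = 0
    out_dir: str = "run"
    generator: GeneratorSettings = GeneratorSettings()
    smoothing: SmoothingSettings = SmoothingSettings()
    clustering: ClusterSettings = ClusterSettings()
    imputation: ImputationSettings = ImputationSettings()
    regression: RegressionSettings = RegressionSettings()

    @classmethod
    def json_schema_str(cls) -> str:
        import json
        return json.dumps(cls.model_json_schema(), indent=2)
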