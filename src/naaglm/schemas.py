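"""Pydantic models for the pipeline's JSON outputs.

Every nested result written by the pipeline is validated through these
models; the generated JSON-schema documents are shipped under
``naaglm/schemas/`` for consumers outside Python.
"""
from __future__ import annotations

from pydantic import BaseModel, Field


class FitJSON(BaseModel):
    columns: list[str]
    coef: list[float]
    covariance: list[list[float]]
    log_likelihood: float
    n_events: int
    n_bins: int
    converged: bool
    regularized: bool
    reliable: bool
    knots: list[float]
    tension: float
    bin_width: float
    burn_in_s: float
    stage_log_rates: dict[str, float | None]
    sdb_multiplier: float | None
    arousal_multiplier: float | None


class FeaturesJSON(BaseModel):
    refractory_s: float | None
    ip_duration_s: float | None
    ip_peak_height: float
    ip_peak_lag_s: float
    ip_peak_width_s: float
    width_mode: str = "half_prominence"


class GofJSON(BaseModel):
    ks_stat: float | None
    threshold: float | None
    n_events: int
    passed: bool
    alpha: float = 0.05


class StageRatesJSON(BaseModel):
    rates_per_hour: dict[str, float | None]
    overall_per_hour: float | None


class PipelineStatusJSON(BaseModel):
    stages: dict[str, str] = Field(description="stage name -> ok/failed/skipped")
    messages: dict[str, str] = {}


def export_schemas(out_dir) -> None:
    """Write each model's JSON schema to ``out_dir``."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for model in (FitJSON, FeaturesJSON, GofJSON, StageRatesJSON, PipelineStatusJSON):
        (out / f"{model.__name__}.json").write_text(
            json.dumps(model.model_json_schema(), indent=2) + "\n"
        )
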