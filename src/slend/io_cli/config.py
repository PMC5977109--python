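"""Run configuration schema (YAML, strictly validated).

Unknown keys are rejected; every output manifest embeds a serialized
copy of the validated config so results remain self-describing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class StoppingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_time: Optional[float] = None
    projectile_separation: Optional[float] = None
    fragment_separation: Optional[float] = None


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["collision", "attachment"] = "collision"
    system: str = Field(description="fixture name or XYZ path")
    basis: str = "sto-3g"
    energy_kev: float = 1.0
    b_list: list[float] = Field(default_factory=lambda: [1.0])
    orientations: int = 1
    seed: int = 0
    aim: str | int = "com"
    separation: float = 30.0
    virtual_offset: int = 0
    spin: Literal["alpha", "beta"] = "alpha"


class DynamicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    etf_mode: Literal["auto", "static", "travelling"] = "auto"
    rtol: float = 1e-7
    atol: float = 1e-9
    max_step: float = 5.0
    energy_tol: float = 1e-3
    record_every: int = 1
    stopping: StoppingConfig = Field(default_factory=StoppingConfig)


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    directory: str = "runs/out"
    text_export: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: ScenarioConfig
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; all schema violations are
    collected and reported at once."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"{path}: invalid config ({exc.error_count()} errors)"]
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"  - {loc}: {err['msg']}")
        raise ConfigError("\n".join(lines)) from None
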