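"""Run configuration: schema, defaults, YAML loading and echoing.

Rates may be written either as fractions (``0.92``) or as percent strings
(``"92%"``), matching how such parameters are usually printed.  Bare
numbers above 1 are rejected rather than silently divided by 100.
"""

from __future__ import annotations

from pathlib import Path
from typing import Annotated, List, Literal, Optional, Tuple, Union

import yaml
from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    ValidationError,
)

from .exceptions import ParameterError
from .model import ModelConfig, OperatingPoint
from .sweeps import SweepSpec, default_grid


def _parse_rate(value):
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return float(text[:-1]) / 100.0
        value = float(text)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValueError(f"expected a fraction or percent string, got {value!r}")
    if value > 1.0:
        raise ValueError(
            f"{value!r} is larger than 1; write a fraction in [0, 1] "
            f"or a percent string like '{value}%'"
        )
    if value < 0.0:
        raise ValueError(f"rate must be non-negative, got {value!r}")
    return float(value)


Rate = Annotated[float, BeforeValidator(_parse_rate)]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReaderConfig(_StrictModel):
    sensitivity: Rate
    specificity: Rate

    def operating_point(self) -> OperatingPoint:
        return OperatingPoint(self.sensitivity, self.specificity)


class TimingConfig(_StrictModel):
    t_abbr: float = Field(262.0, gt=0, description="abbreviated duration [s]")
    t_full: float = Field(776.0, gt=0, description="full duration [s]")


class BandConfig(_StrictModel):
    interval: Tuple[Rate, Rate] = (0.75, 0.91)
    mode: Literal["emulation", "restricted_limits"] = "emulation"


class SweepConfig(_StrictModel):
    parameter: Literal[
        "ai_sensitivity",
        "ai_specificity",
        "rad_sensitivity_abbr",
        "rad_specificity_abbr",
        "t_full",
        "t_abbr",
    ] = "ai_specificity"
    grid: Optional[List[float]] = None
    num: int = Field(1001, ge=2)
    normalized: bool = False


class CohortConfig(_StrictModel):
    size: int = Field(1_000_000, gt=0)
    seed: int = 0
    sampling: Literal["expected_counts", "multinomial"] = "expected_counts"
    n_random_couplings: int = Field(100, ge=0)


class RunConfig(_StrictModel):
    """Validated configuration for a model run; absent keys take defaults."""

    radiologist_abbreviated: ReaderConfig = ReaderConfig(
        sensitivity=0.90, specificity=0.92
    )
    radiologist_full: ReaderConfig = ReaderConfig(sensitivity=0.92, specificity=0.95)
    ai: ReaderConfig = ReaderConfig(sensitivity=0.80, specificity=0.80)
    prevalence: Rate = 0.0146
    timing: TimingConfig = TimingConfig()
    band: BandConfig = BandConfig()
    sweep: SweepConfig = SweepConfig()
    cohort: CohortConfig = CohortConfig()
    output_dir: str = "results"

    def model_parameters(self) -> ModelConfig:
        return ModelConfig(
            rad_abbr=self.radiologist_abbreviated.operating_point(),
            rad_full=self.radiologist_full.operating_point(),
            ai=self.ai.operating_point(),
            prevalence=self.prevalence,
            t_abbr=self.timing.t_abbr,
            t_full=self.timing.t_full,
        )

    def sweep_spec(self) -> SweepSpec:
        grid = self.sweep.grid
        if grid is None:
            grid = default_grid(
                self.sweep.parameter, self.model_parameters(), self.sweep.num
            )
        return SweepSpec(
            parameter=self.sweep.parameter,
            grid=tuple(grid),
            fixed=self.model_parameters(),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load and validate a YAML/JSON config file; ``None`` gives defaults.

    Unknown keys and invariant violations raise :class:`ParameterError`
    naming the offending key.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"config file {path} failed to parse: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config file {path} must contain a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ParameterError(f"invalid configuration: {details}") from exc


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(config.to_yaml())
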