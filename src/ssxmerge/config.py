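"""Pipeline configuration: a strict, serialisable parameter block.

Every threshold the selection/merging procedure uses lives here with its
default (ISa cutoff 3.0, CC1/2 threshold 0.3, 2%/2 deg cell tolerances).
Unknown keys are rejected so a typo in a config file cannot silently fall
back to a default, and the parsed config is echoed into every report for
provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .symmetry import UnitCell

__all__ = ["PipelineConfig", "load_config"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ref_cell: tuple[float, float, float, float, float, float]
    space_group: str = "C2221"
    length_tol: float = Field(0.02, gt=0)
    angle_tol: float = Field(2.0, gt=0)
    isa_cutoff: float = Field(3.0, ge=0)
    cc_threshold: float = Field(0.3, ge=0)
    n_shells: int = Field(10, ge=1)
    shell_scheme: str = "equal_volume"
    n_splits: int = Field(10, ge=1)
    seed: int = 0
    min_pairs: int = Field(50, ge=10)
    merge_friedel: bool = True
    iterate_rejection: bool = False
    element_cutoffs: dict[str, float] = Field(
        default_factory=lambda: {"ZN": 2.6, "CA": 3.0}
    )

    @field_validator("shell_scheme")
    @classmethod
    def _scheme(cls, v: str) -> str:
        if v not in ("equal_volume", "equal_count"):
            raise ValueError("shell_scheme must be equal_volume or equal_count")
        return v

    def cell(self) -> UnitCell:
        return UnitCell(*self.ref_cell)

    def echo(self) -> dict:
        # JSON-mode dump so the echoed block round-trips through report files
        return self.model_dump(mode="json")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
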