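"""Run configuration: a validated, versioned, JSON-round-trippable schema.

Every analysis run is fully determined by (input data, AnalysisConfig), so a
config exported from one run reproduces it exactly. Unknown keys on read are
errors, not warnings: silently ignoring a misspelled parameter would break
reproducibility in the worst possible way.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

CONFIG_SCHEMA_VERSION = "1"


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema."""


class AnalysisConfig(BaseModel):
    """All tunable parameters of a batch analysis run.

    ``diameter_px`` is the expected synapse diameter in pixels (default 100);
    ``pre_inference_scale`` shrinks images before segmentation inference, with
    the diameter adjusted automatically so the same physical size is targeted.
    Filter ranges are inclusive on both ends.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    input_root: Path
    output_dir: Path
    segmentation_channel: str
    condition_labels: dict[str, str] = Field(default_factory=dict)
    channel_names: Optional[list[str]] = None
    backend: str = "builtin"
    diameter_px: float = Field(default=100.0, gt=0)
    pre_inference_scale: float = Field(default=0.7, ge=0.3, le=1.0)
    diameter_filter: tuple[float, float] = (0.0, 1e9)
    circularity_filter: tuple[float, float] = (0.0, 1.0)
    radial_target_length: int = Field(default=100, ge=2)
    scale_profiles: bool = True
    radial_mask_only: bool = False
    normalize_profiles: bool = True
    pcc_on_raw: bool = False
    guard_band_px: int = Field(default=5, ge=0)
    reference_condition: Optional[str] = None
    exclude_border_cells: bool = False
    rng_seed: int = 0
    version: str = CONFIG_SCHEMA_VERSION

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        for name in ("diameter_filter", "circularity_filter"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
        if self.channel_names is not None:
            if len(set(self.channel_names)) != len(self.channel_names):
                raise ValueError(f"channel_names not unique: {self.channel_names}")
            if self.segmentation_channel not in self.channel_names:
                raise ValueError(
                    f"segmentation_channel {self.segmentation_channel!r} "
                    f"not in channel_names {self.channel_names}"
                )
        return self


def write_config(config: AnalysisConfig, path: Path | str) -> None:
    """Write the config as a JSON document (sorted keys, stable formatting)."""
    data = config.model_dump(mode="json")
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_config(path: Path | str) -> AnalysisConfig:
    """Read and validate a JSON config; unknown or invalid keys are fatal."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path}: not valid JSON: {e}") from e
    try:
        return AnalysisConfig(**data)
    except ValidationError as e:
        fields = ", ".join(".".join(str(p) for p in err["loc"]) or "<root>" for err in e.errors())
        raise ConfigError(f"{path}: invalid configuration (offending fields: {fields})\n{e}") from e
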