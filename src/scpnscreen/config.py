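"""Pipeline configuration: validated parameter blocks plus TOML round-trip.

Every analysis parameter defaults to the printed screen value where one
exists (segmentation parameters, viability criteria, intensity bands);
everything else is an explicit, documented default. ``to_toml`` /
``from_toml`` round-trip deterministically, and the SHA-256 of the
canonical TOML serves as the run manifest's config hash.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, Field

from .classify import ThresholdPolicy
from .qc import ToxicityCutoffs, ViabilityCriteria
from .segment import SegmentationParams
from .simulate import DEFAULT_CHANNEL_MAP
from .triage import TriageCriteria

__all__ = ["PathsConfig", "QCConfig", "ScoringConfig", "PipelineConfig",
           "from_toml", "to_toml", "config_hash"]


class PathsConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    image_dir: str = "images"
    plate_map: str = "plate_map.csv"
    out_dir: str = "results"


class QCConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    control_condition: str = "dmso"
    viability: ViabilityCriteria = ViabilityCriteria()
    toxicity: ToxicityCutoffs = ToxicityCutoffs()


class ScoringConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    ratio_baseline: str = "untreated"
    ctip2_baseline: str = "fezf2_modrna"
    satb2_baseline: str = "gfp_modrna"
    comparison_baseline: str = "dmso"
    pair: tuple[str, str] = ("CTIP2", "SATB2")
    equal_var: bool = True  # Student t; False selects Welch


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    paths: PathsConfig = PathsConfig()
    seed: int = 0
    pixel_scale_um: float = Field(default=0.65, gt=0)
    bit_depth: int = Field(default=12, gt=0, le=16)
    channel_map: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    segmentation: SegmentationParams = SegmentationParams()
    qc: QCConfig = QCConfig()
    classification: ThresholdPolicy = ThresholdPolicy()
    scoring: ScoringConfig = ScoringConfig()
    triage: TriageCriteria = TriageCriteria()


def from_toml(path: str | Path) -> PipelineConfig:
    import tomllib

    with open(path, "rb") as fh:
        return PipelineConfig(**tomllib.load(fh))


def _fmt_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def _emit(table: dict, prefix: str, lines: list[str]) -> None:
    scalars = {k: v for k, v in table.items()
               if not isinstance(v, dict) and v is not None}
    subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
    if scalars or not subtables:
        if prefix:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            key = k if k.replace("_", "").replace("-", "").isalnum() else f'"{k}"'
            lines.append(f"{key} = {_fmt_scalar(v)}")
        lines.append("")
    for k, v in subtables.items():
        key = k if k.replace("_", "").replace("-", "").isalnum() else f'"{k}"'
        _emit(v, f"{prefix}.{key}" if prefix else key, lines)


def to_toml(config: PipelineConfig) -> str:
    """Canonical TOML text (deterministic key order; parse -> emit idempotent)."""
    dump = config.model_dump(mode="json")
    lines: list[str] = []
    _emit(dump, "", lines)
    return "\n".join(lines).rstrip() + "\n"


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(to_toml(config).encode()).hexdigest()
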