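"""Validated YAML configuration for every pipeline stage.

The schema is strict: unknown keys and out-of-range values are rejected with
the offending dotted path. An empty file yields the full default
configuration. The shipped ``configs/reference.yaml`` records the
full-scale reference settings (256-cube patches, 200,000 steps); the code
defaults here are the desk-scale settings actually exercised by the tests.
"""

from __future__ import annotations

import zlib
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhantomSection(_Strict):
    shape: tuple[int, int, int] = (64, 64, 64)
    region_z_fractions: tuple[float, float] = (1 / 3, 2 / 3)
    aorta_radius_range: tuple[float, float] = (4.0, 5.5)
    carotid_radius_range: tuple[float, float] = (2.0, 2.8)
    intracranial_radius_range: tuple[float, float] = (1.0, 1.6)
    intracranial_depth: int = Field(2, ge=1)
    background_intensity: float = 40.0
    vessel_intensity: float = 250.0
    bone_intensity: float = 300.0
    noise_sigma: float = Field(15.0, ge=0)
    skull_thickness: float = Field(2.5, gt=0)
    bone_vessel_clearance: float = Field(2.0, ge=0)


class AugmentSection(_Strict):
    allow_flip: bool = True
    max_rotation_deg: float = Field(25.0, ge=0)
    max_shift: int = Field(20, ge=0)
    occlusion_size_range: tuple[int, int] = (4, 12)
    occlusion_prob: float = Field(0.5, ge=0, le=1)
    noise_sigma: float = Field(10.0, ge=0)
    expansion_factor: int = Field(5, ge=1)


class NetworkSection(_Strict):
    base_width: int = Field(8, ge=1)
    levels: int = Field(4, ge=1)
    n_blocks: int = Field(8, ge=1)
    negative_slope: float = Field(0.1, ge=0)


class TrainSection(_Strict):
    momentum: float = Field(0.9, ge=0, lt=1)
    weight_decay: float = Field(0.0001, ge=0)
    learning_rate: float = Field(0.01, gt=0)
    lr_decay: float = Field(0.99995, gt=0, le=1)
    steps: int = Field(2000, ge=1)
    batch_size: int = Field(1, ge=1)
    patch_size: int = Field(32, ge=8)
    centerline_weight_factor: float = Field(2.0, ge=1)
    steps_bone: int = Field(700, ge=1)
    refine_steps: int = Field(400, ge=1)
    steps_vessel: int = Field(500, ge=1)
    steps_repair: int = Field(600, ge=1)


class PatchSection(_Strict):
    patch_size: int = Field(256, ge=1)
    stride: Optional[int] = None
    reduce: str = Field("mean", pattern="^(mean|max)$")


class CascadeSection(_Strict):
    region_fractions: tuple[float, float] = (1 / 3, 2 / 3)
    threshold: float = Field(0.5, ge=0, le=1)
    intensity_scale: float = Field(300.0, gt=0)
    background_fill: float = 40.0
    corridor_radius: int = Field(5, ge=1)
    min_component_size: int = Field(8, ge=1)
    target_spacing: Optional[float] = Field(0.5, gt=0)


class Config(_Strict):
    phantom: PhantomSection = PhantomSection()
    augment: AugmentSection = AugmentSection()
    network: NetworkSection = NetworkSection()
    train: TrainSection = TrainSection()
    patch: PatchSection = PatchSection()
    cascade: CascadeSection = CascadeSection()
    seed: int = 0


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def load_config(path=None, overrides: dict | None = None) -> Config:
    """Load and validate a YAML config; missing keys get defaults."""
    raw = {}
    if path is not None:
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        raw = _deep_merge(raw, overrides)
    try:
        return Config(**raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def dump_config(config: Config, path=None) -> str:
    text = yaml.safe_dump(config.model_dump(), sort_keys=False)
    if path is not None:
        with open(str(path), "w") as fh:
            fh.write(text)
    return text


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministically fan one global seed out to per-stage seeds (< 2^31)."""
    return (int(master_seed) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF
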