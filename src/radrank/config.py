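"""Run configuration: parsing, defaults, and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .phantom import PhantomSpec


@dataclass
class RunConfig:
    """Everything needed for one end-to-end reproducibility run.

    The cohort comes either from the phantom generator (``phantom``) or
    from an on-disk manifest (``manifest``); exactly one must be set.
    The reference arm is the global uniform quantizer at ``levels``
    gray levels; the individual quantizer at the same level count is
    compared against it under both threshold states and both
    aggregation dialects.
    """

    phantom: Optional[PhantomSpec] = field(default_factory=PhantomSpec)
    manifest: Optional[str] = None
    levels: int = 128
    threshold_lo_hu: float = -200.0
    threshold_hi_hu: float = 300.0
    cutoffs: tuple[float, ...] = (0.75, 0.8)
    resample_enabled: bool = False
    resample_spacing_mm: float = 1.0
    out_dir: str = "radrank_out"
    log_level: str = "INFO"
    dump_matrices: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        phantom_raw = raw.pop("phantom", None)
        manifest = raw.pop("manifest", None)
        known = {f.name for f in fields(cls)} - {"phantom", "manifest"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(float(c) for c in raw["cutoffs"])
        phantom = None
        if manifest is None:
            phantom = PhantomSpec(**phantom_raw) if phantom_raw else PhantomSpec()
        elif phantom_raw is not None:
            raise ConfigError("set either 'phantom' or 'manifest', not both")
        return cls(phantom=phantom, manifest=manifest, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable violations (empty = valid)."""
    violations = []
    if (config.phantom is None) == (config.manifest is None):
        violations.append("exactly one of phantom / manifest must be set")
    if config.levels < 2:
        violations.append(f"levels >= 2 required, got levels = {config.levels}")
    if not config.cutoffs:
        violations.append("at least one cutoff is required")
    for c in config.cutoffs:
        if not 0 < c <= 1:
            violations.append(f"cutoffs must lie in (0,1], got {c}")
    if not config.threshold_lo_hu < config.threshold_hi_hu:
        violations.append(
            f"threshold window requires lo < hi, got "
            f"[{config.threshold_lo_hu}, {config.threshold_hi_hu}]"
        )
    if config.resample_enabled and config.resample_spacing_mm <= 0:
        violations.append(
            f"resample.spacing_mm must be > 0, got {config.resample_spacing_mm}"
        )
    return violations
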