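"""Run configuration: a flat YAML schema with CLI-flag overrides."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

VALID_DETECTORS = ("oracle", "blob", "capacity", "from_files")


@dataclass
class RunConfig:
    tile_size_px: int = 100
    tolerance_px: float = 2.0
    ro_min: float = 0.25
    margin_px: float = 4.0
    no_dedup: bool = False
    detector: str = "oracle"
    detector_params: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def validate(self) -> None:
        if self.tile_size_px < 1:
            raise ValueError(f"tile_size_px must be >= 1, got {self.tile_size_px}")
        if self.tolerance_px < 0:
            raise ValueError(f"tolerance_px must be >= 0, got {self.tolerance_px}")
        if not (0.0 <= self.ro_min <= 1.0):
            raise ValueError(f"ro_min must be in [0, 1], got {self.ro_min}")
        if self.margin_px < 0:
            raise ValueError(f"margin_px must be >= 0, got {self.margin_px}")
        if self.detector not in VALID_DETECTORS:
            raise ValueError(
                f"detector must be one of {VALID_DETECTORS}, got {self.detector!r}"
            )

    @classmethod
    def load(
        cls, yaml_path: Optional[Path] = None, overrides: Optional[Dict[str, Any]] = None
    ) -> "RunConfig":
        """Build a config from an optional YAML file plus overrides.

        Unknown keys in either source are rejected; overrides with value
        ``None`` are ignored (an unset CLI flag).
        """
        known = {f.name for f in fields(cls)}
        data: Dict[str, Any] = {}
        if yaml_path is not None:
            raw = yaml.safe_load(Path(yaml_path).read_text())
            if raw is None:
                raw = {}
            if not isinstance(raw, dict):
                raise ValueError(f"{yaml_path}: config must be a mapping")
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"{yaml_path}: unknown config keys {sorted(unknown)}")
            data.update(raw)
        for key, value in (overrides or {}).items():
            if value is None:
                continue
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            data[key] = value
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> Dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
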