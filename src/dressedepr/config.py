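"""Run configuration: YAML/JSON files mirroring the parameter dataclasses.

A config file has top-level sections named after the objects they
configure; keys inside each section mirror the dataclass field names.
Unknown sections or keys are rejected outright — a silently ignored typo
in a physics parameter is worse than an error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .locksim import EnsembleSpec
from .sequence import DriveParams
from .spins import SpinPairParams

__all__ = ["RunConfig", "load_config"]

_SECTION_TYPES = {
    "pair": SpinPairParams,
    "drive": DriveParams,
    "ensemble": EnsembleSpec,
}

_PROCESSING_KEYS = {"window", "zerofill_factor", "prominence", "edge_frac",
                    "modulation_fit", "time_scale"}


@dataclass
class RunConfig:
    """Validated configuration for a CLI run."""

    pair: SpinPairParams | None = None
    drive: DriveParams | None = None
    ensemble: EnsembleSpec | None = None
    processing: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."

    def describe(self) -> dict[str, Any]:
        """Full parameter dump (defaults included) for the run log."""
        out: dict[str, Any] = {"seed": self.seed, "outdir": self.outdir,
                               "processing": dict(self.processing)}
        for name in ("pair", "drive", "ensemble"):
            obj = getattr(self, name)
            out[name] = dataclasses.asdict(obj) if obj is not None else None
        return out


def _build_section(name: str, data: dict[str, Any]):
    cls = _SECTION_TYPES[name]
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in section '{name}': {sorted(unknown)}")
    # tuples arrive from YAML as lists
    clean = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**clean)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    cfg = RunConfig()
    for key, value in data.items():
        if key in _SECTION_TYPES:
            setattr(cfg, key, _build_section(key, value or {}))
        elif key == "processing":
            unknown = set(value or {}) - _PROCESSING_KEYS
            if unknown:
                raise ValueError(
                    f"unknown keys in section 'processing': {sorted(unknown)}")
            cfg.processing = dict(value or {})
        elif key == "seed":
            cfg.seed = int(value)
        elif key == "outdir":
            cfg.outdir = str(value)
        else:
            raise ValueError(f"unknown top-level config key '{key}'")
    return cfg
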