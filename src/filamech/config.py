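"""Hierarchical run configuration with strict key validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

from .kinetics import AnalysisWindows
from .wlc import KBT_ROOM


@dataclass(frozen=True)
class RunConfig:
    """Every tunable threshold of the pipeline in one validated record.

    Unknown keys in a config file are rejected outright, so a typo can never
    silently fall back to a default.  A provenance stamp (config hash and
    package version) is written into every report produced under this
    config.
    """

    kbt: float = KBT_ROOM
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    wlc_jump_threshold: float = 50.0  # nm, rupture-force jump detection
    hill_n_boot: int = 1000
    hill_sigma_floor: float = 1e-3
    classify_floor_frac: float = 0.25
    coilable_slope_sigma: float = 3.0
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "windows" in data and isinstance(data["windows"], dict):
            wkeys = {f.name for f in fields(AnalysisWindows)}
            wunknown = set(data["windows"]) - wkeys
            if wunknown:
                raise ValueError(f"unknown windows key(s): {sorted(wunknown)}")
            data["windows"] = AnalysisWindows(**data["windows"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def stamp(self) -> dict:
        from . import __version__
        payload = json.dumps(asdict(self), sort_keys=True)
        return {
            "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
            "package_version": __version__,
        }
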