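"""YAML config loading for scaffold specs, print settings and profiles.

Config files are flat ``key: value`` mappings whose keys match the
dataclass fields (units: mm, mm/min, °C).  Unknown keys are rejected to
catch typos early.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .extrusion import ExtrusionParams
from .gcode import PrintSettings
from .geometry import ScaffoldSpec
from .validation import PrinterProfile

__all__ = [
    "load_scaffold_spec",
    "load_print_settings",
    "load_printer_profile",
    "load_extrusion_params",
    "from_dict",
]

_TUPLE_FIELDS = {"origin", "angle_sequence", "xyz_resolution"}


def from_dict(cls, data: dict):
    """Instantiate a config dataclass from a flat mapping."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def _load(path, cls):
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    return from_dict(cls, data)


def load_scaffold_spec(path) -> ScaffoldSpec:
    return _load(path, ScaffoldSpec)


def load_print_settings(path) -> PrintSettings:
    return _load(path, PrintSettings)


def load_printer_profile(path) -> PrinterProfile:
    return _load(path, PrinterProfile)


def load_extrusion_params(path) -> ExtrusionParams:
    return _load(path, ExtrusionParams)
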