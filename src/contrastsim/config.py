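"""Pipeline configuration: defaults, YAML loading, validation.

A single YAML file configures the whole pipeline; any subset of keys may be
given and is merged over the defaults below.  Unknown keys raise a
:class:`ConfigError` naming the offending key, so typos fail loudly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

__all__ = ["ConfigError", "PipelineConfig", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    pass


DEFAULTS: Dict[str, Any] = {
    "materials": {
        # per-cavity iodine concentration, mg I / mL
        "iodine_mg_per_ml": 23.35,
        # computational solutions are defined at unit density
        "simulation_density": 1.00,
        # measured density of the experimental solutions, g/cm^3
        "experiment_density": 1.04,
    },
    "phantom": {
        "slab_thickness_mm": 45.0,
        "disk_radius_mm": 10.0,
        "disk_count": 14,
        "thickness_range_mm": [0.2, 2.6],
    },
    "wellplate": {
        "volumes_ml": [0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1],
        "well_diameter_mm": 6.4,
        "well_pitch_mm": 9.0,
        "base_thickness_mm": 1.0,
    },
    "spectra": {
        # bundled fixture names for the simulation beams; user-supplied
        # tabulated files (name -> path) take precedence over fixtures
        "simulation": ["rh_rh_35kvp", "w_al_100kvp"],
        "files": {},
    },
    "geometry": {
        "simulation": {"d1_mm": 1000.0, "d2_mm": 1300.0,
                       "pitch_mm": 0.8, "shape": [500, 500]},
        "radiograph": {"d1_mm": 1000.0, "d2_mm": 1100.0,
                       "pitch_mm": 0.148, "shape": [380, 1240]},
    },
    "acquisition": {
        "kvps": [46.0, 80.0, 95.0, 100.0],
        "replicates": 1,
        "seed": 0,
        "aec_target": 39321.0,
        "photons_background": 10000.0,
        "noise": True,
    },
    "analysis": {
        "roi_pixels": 1124,
        "reference_row": "B",
        "footprint_fraction": 0.5,
    },
    "output": {"dir": "out"},
}


def _merge(base: Dict[str, Any], override: Dict[str, Any], path: str = "") -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {where!r}")
        if isinstance(base[key], dict) and path != "spectra":
            if not isinstance(value, dict):
                raise ConfigError(f"configuration key {where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def _merge_spectra(base, override):
    # spectra.files is an open mapping (any name -> path)
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in ("simulation", "files"):
            raise ConfigError(f"unknown configuration key: spectra.{key!r}")
        out[key] = value
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (see ``DEFAULTS`` for the schema)."""

    data: Dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def spectrum(self, name: str):
        """Resolve a spectrum by name: user file first, fixture second."""
        from .spectra import fixture_spectrum, load_spectrum

        files = self["spectra"]["files"]
        if name in files:
            path = Path(files[name])
            if not path.exists():
                raise ConfigError(
                    f"spectra.files[{name!r}] points to missing file {path}")
            return load_spectrum(path, label=name)
        try:
            return fixture_spectrum(name)
        except KeyError:
            raise ConfigError(
                f"spectrum {name!r} is neither in spectra.files nor a bundled fixture")


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` gives pure defaults."""
    if path is None:
        return PipelineConfig(copy.deepcopy(DEFAULTS))
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level configuration must be a mapping")
    merged = copy.deepcopy(DEFAULTS)
    for key, value in raw.items():
        if key not in DEFAULTS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        if key == "spectra":
            merged[key] = _merge_spectra(DEFAULTS[key], value)
        elif isinstance(DEFAULTS[key], dict):
            merged[key] = _merge(DEFAULTS[key], value, key)
        else:
            merged[key] = value
    return PipelineConfig(merged)
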