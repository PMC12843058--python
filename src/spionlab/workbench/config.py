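"""YAML run configuration with strict schema validation.

Unknown keys are rejected before any computation runs; unit suffixes are
part of the key names so a config is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


# allowed keys per block; None marks a scalar leaf
SCHEMA: dict = {
    "seed": None,
    "output_dir": None,
    "log_level": None,
    "particle": {
        "core_diameter_nm": None,
        "hydrodynamic_diameter_nm": None,
        "hydrodynamic_ratio": None,
        "anisotropy_kj_per_m3": None,
        "core_saturation_magnetization_ka_per_m": None,
        "attempt_time_s": None,
        "core_density_kg_per_m3": None,
    },
    "medium": {"viscosity_pa_s": None, "temperature_k": None},
    "excitation": {
        "frequency_khz": None,
        "induction_mt": None,
        "amplitude_a_per_m": None,
    },
    "suspension": {
        "number_density_per_m3": None,
        "mass_concentration_mg_per_ml": None,
    },
    "thermal": {
        "specific_heat_j_per_kg_k": None,
        "density_kg_per_m3": None,
        "concentration_mg_per_ml": None,
    },
    "relaxometry": {
        "field_t": None,
        "water_diffusion_m2_per_s": None,
    },
    "sweep": {"diameters_nm": None},
    "tem": {
        "median_radius_px": None,
        "closing_radius_px": None,
        "min_marker_distance_px": None,
        "exclude_border": None,
        "bin_width_nm": None,
        "pixel_size_nm": None,
    },
    "synth": {
        "median_diameter_nm": None,
        "geometric_sd": None,
        "n_particles": None,
        "image_size_px": None,
        "touching_fraction": None,
        "noise_sd": None,
    },
    "study": {"plateau_fraction": None, "bonferroni": None},
}


def validate_config(cfg: dict, schema: dict = SCHEMA, path: str = "") -> None:
    """Recursively reject keys not present in the schema."""
    if not isinstance(cfg, dict):
        raise ConfigError(f"config block {path or '<root>'} must be a mapping")
    for key, value in cfg.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in schema:
            raise ConfigError(f"unknown config key: {where}")
        sub = schema[key]
        if isinstance(sub, dict):
            validate_config(value, sub, where)


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


DEFAULT_DEMO_CONFIG: dict = {
    "seed": 0,
    "particle": {
        "anisotropy_kj_per_m3": 21.0,
        "core_saturation_magnetization_ka_per_m": 300.0,
        "hydrodynamic_ratio": 1.5,
        "attempt_time_s": 1e-9,
    },
    "medium": {"viscosity_pa_s": 8.9e-4, "temperature_k": 310.0},
    "excitation": {"frequency_khz": 58.3, "induction_mt": 20.0},
    "thermal": {
        "specific_heat_j_per_kg_k": 4000.0,
        "density_kg_per_m3": 1000.0,
        "concentration_mg_per_ml": 25.0,
    },
    "relaxometry": {"field_t": 0.55, "water_diffusion_m2_per_s": 2.3e-9},
    "sweep": {"diameters_nm": [10.0, 15.0, 20.0, 22.0, 25.0, 30.0]},
    "synth": {
        "median_diameter_nm": 12.0,
        "geometric_sd": 1.2,
        "n_particles": 150,
        "image_size_px": 768,
        "touching_fraction": 0.0,
        "noise_sd": 3.0,
    },
    "study": {"plateau_fraction": 0.05, "bonferroni": False},
}
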