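"""Run configuration: defaults, YAML loading, and strict validation.

Defaults encode the study conditions each synthetic stage emulates (group
means, rates, biases); unknown keys are rejected with the offending paths
so typos never silently fall back to defaults.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genotypes": ["wt", "mut"],
    "morpho": {
        "n_per_class": 40,
        "prominence_frac": 0.2,
        "d0_um": 150.0,
        "sholl_step_um": 20.0,
        "kmeans_n_init": 50,
    },
    "cluster": {
        "n_per_class": 40,
        "n_components": 2,
        "kmeans_n_init": 50,
        "elbow_k_max": 6,
    },
    "ephys": {
        "rin_MOhm": 150.0,
        "sag_index": 0.8,
        "washin_factors": {"complex": 0.525, "simple": 0.756},
        "washin_n_cells": 8,
        "event_cv": 0.1,
        "ie_ratio_means": {"complex": 3.15, "simple": 5.70},
        "ie_n_cells": 23,
    },
    "puncta": {
        "biases": {"pv": 0.74, "cb1r": 1.32},
        "n_scenes": 5,
        "puncta_rate_per_soma": 12.0,
    },
    "lfp": {
        "f0_hz": {"wt": 25.0, "mut": 31.0},
        "lag_ms": {"wt": 1.0, "mut": -1.8},
        "drug_power_factor": {"wt": 0.93, "mut": 1.02},
        "n_experiments": 6,
        "duration_s": 60.0,
        "snr": 5.0,
        "gamma_band_hz": [18.0, 50.0],
        "max_lag_ms": 25.0,
    },
    "census": {
        "p_marker": {"wt": [0.089, 0.251], "mut": [0.18, 0.044]},
        "n_cells_per_band": [100, 100],
        "bin_um": 20.0,
        "coloc_p": 0.54,
        "coloc_n": 48,
    },
}

STAGES = ["morpho", "cluster", "ephys", "puncta", "lfp", "census"]


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def validate_config(cfg: dict) -> dict:
    """Merge onto the defaults, rejecting unknown keys."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return _merge(DEFAULT_CONFIG, cfg)


def load_config(path=None) -> dict:
    """Load and validate a YAML run configuration (defaults when ``path`` is None)."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)
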