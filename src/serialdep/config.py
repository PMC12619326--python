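"""Validated configuration with literature defaults.

The default configuration carries the parameter values used throughout the
package: Bayesian observer sigma_s = 16.9 deg, gamma = 2.6, p_same = 0.64,
per-trial noise levels {6, 9, 12} deg; Demixing Model noise grids
(current-item sigma 12..28 deg in steps of 4, previous-item sigma
{40, 60, 80} deg), temporal SD 20 with d' = 1, N = 100 measurements, equal
mixing weights; analysis bandwidth 10 deg and alpha 0.05.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "dump_config", "ConfigError"]


DEFAULT_CONFIG: dict = {
    "observer": {
        "sigma_s": 16.9,
        "gamma": 2.6,
        "p_same": 0.64,
        "grid_step": 0.5,
        "noise_levels": [6.0, 9.0, 12.0],
    },
    "demixing": {
        "sigma11_list": [12.0, 16.0, 20.0, 24.0, 28.0],
        "sigma12_list": [40.0, 60.0, 80.0],
        "sigma_temp": 20.0,
        "dprime_temp": 1.0,
        "n_meas": 100,
        "pi1": 0.5,
        "n_restarts": 10,
    },
    "analysis": {
        "bandwidth": 10.0,
        "alpha": 0.05,
        "outlier_sd_mult": 3.0,
        "exclusion_circ_sd": 30.0,
    },
    "power": {
        "n_sims": 1000,
        "effect_difference": 1.0,
        "baseline_amplitude": 2.0,
        "width": 35.0,
        "alpha": 0.05,
        "response_sd": 9.0,
        "participant_amp_sd": 0.5,
    },
}

_RANGES = {
    ("observer", "sigma_s"): (0.0, None, False),
    ("observer", "gamma"): (0.0, None, False),
    ("observer", "p_same"): (0.0, 1.0, True),
    ("observer", "grid_step"): (0.0, 180.0, False),
    ("analysis", "bandwidth"): (0.0, None, False),
    ("analysis", "alpha"): (0.0, 0.5, False),
    ("power", "alpha"): (0.0, 0.5, False),
    ("power", "effect_difference"): (None, None, True),
    ("demixing", "pi1"): (0.0, 1.0, False),
}


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


def _validate(cfg: dict) -> None:
    errors = []
    for section, values in cfg.items():
        if section not in DEFAULT_CONFIG:
            errors.append(f"unknown section {section!r}")
            continue
        for key, val in values.items():
            if key not in DEFAULT_CONFIG[section]:
                errors.append(f"unknown key {section}.{key}")
                continue
            rng = _RANGES.get((section, key))
            if rng is not None and isinstance(val, (int, float)):
                lo, hi, inclusive = rng
                if lo is not None and (val < lo or (not inclusive and val == lo)):
                    errors.append(f"{section}.{key} = {val} below valid range")
                if hi is not None and (val > hi or (not inclusive and val == hi)):
                    errors.append(f"{section}.{key} = {val} above valid range")
    if errors:
        raise ConfigError("; ".join(errors))


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON config file, fill defaults, reject unknown keys.

    With ``path=None`` (or an empty file) the full default configuration is
    returned.  ``overrides`` is an optional in-memory dict merged last.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            user = json.loads(text) if text.strip() else {}
        else:
            user = yaml.safe_load(text) or {}
    for extra in (user, overrides or {}):
        _validate(extra)
        for section, values in extra.items():
            cfg[section].update(values)
    _validate(cfg)
    return cfg


def dump_config(cfg: dict, path) -> None:
    """Write a config dict to YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
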