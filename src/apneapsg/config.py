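"""Run configuration: defaults plus YAML overrides.

The configuration is a plain nested dictionary so that a run log can print
it verbatim and a run can be reproduced from the log alone.  CLI flags
override file values, which override the defaults below.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "synth": {
        "n_patients": 5,
        "minutes_per_patient": 200,
        "apnea_fraction": 0.4,
        "rr_effect": 100.0,
        "desat_depth": 6.0,
        "desat_recovery_s": 8.0,
        "airflow_drop": 0.9,
        "abdo_gain": 2.0,
        "normal_patient_indices": [],
    },
    "selection": {
        "alpha": 0.05,
    },
    "evaluation": {
        "k": 10,
        "r_values": [0.2, 1.0, 10.0],
        "degrees": [2, 3, 4],
        "sigmas": [1.0, 5.0, 25.0],
    },
    "io": {
        "reader": "csv",  # csv | wfdb
    },
}


def deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = deep_update(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults merged with an optional YAML override file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        cfg = deep_update(cfg, override)
    return cfg
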