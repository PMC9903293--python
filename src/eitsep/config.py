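"""Run configuration: defaults, YAML round-trip, resolution.

Every field has a default; a fully-resolved copy is written alongside every
pipeline output directory so any run can be reproduced from its artifacts.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: Defaults for the full simulate -> separate -> reconstruct -> score run.
#: The phantom section mirrors the simulated-breathing study: heart fixed at
#: radius 0.3 / conductivity 2, lungs at conductivity 0.5 against background
#: 1.0 with the radius swept; the single-frame default probes the maximal
#: expansion state (lung radius 0.6) where cardiac suppression is strongest.
DEFAULTS: dict = {
    "mesh": {
        "dimension": 2,
        "n_electrodes": 16,
        "target_element_size": 0.08,
        "height": 1.0,
        "electrode_half_width_deg": 4.0,
        "jitter": 0.0,
    },
    "phantom": {
        "heart_radius": 0.3,
        "heart_conductivity": 2.0,
        "lung_conductivity": 0.5,
        "background_conductivity": 1.0,
        "heart_center": None,          # null -> package default
        "left_lung_center": None,
        "right_lung_center": None,
        "lung_radius_start": 0.6,
        "lung_radius_end": 0.6,
        "n_frames": 1,
    },
    "protocol": {
        "n_electrodes": 16,
    },
    "separation": {
        "pca_component": 4,            # 1-based: PC4
        "emd_component": 1,            # 1-based: IMF1
        "lung_gain": 1.01,
        "emd": {
            "sd_threshold": 0.2,
            "max_sifts": 10,
            "n_mirror": 2,
        },
    },
    "inverse": {
        "hyperparameter": 0.05,
        "prior": "noser",
        "grid_size": 32,
        "slab_half_width": 0.15,
    },
    "metrics": {
        "weighted_centroid": True,
    },
    "noise_std": 0.0,
    "seed": 0,
    "output_dir": "eitsep_run",
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def resolve_config(overrides: dict | None = None) -> dict:
    """Full configuration with defaults applied under ``overrides``."""
    return _merge(DEFAULTS, overrides or {})


def load_config(path) -> dict:
    """Read a YAML config file and resolve it against the defaults."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return resolve_config(data)


def save_config(config: dict, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
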