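"""Structured pipeline configuration with strict validation.

One YAML file configures every stage; unknown sections or keys are
rejected by name before any computation runs. Analysis-procedure parameters keep their reference defaults (tau = 7 s, responder percentile
95, exemplar pruning at 10 members, KDE bandwidth factor 0.75,
20 classifier repeats with 1,000-per-type upsampling, t/f-cluster minimum
size 10); scale knobs (cell counts, shuffle counts, grid size) default to
a desk-scale demo.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "synthetic": {
        "n_types": 6,
        "layer_assignment": [0, 0, 1, 1, 2, 2],
        "layer_depths": [[0.0, 20.0], [25.0, 45.0], [50.0, 70.0]],
        "extent_um": [300.0, 200.0],
        "mosaic_exclusion_radius": 6.0,
        "ap_gradient": None,
        "n_cells_per_type": 100,
        "n_archetypes": 5,
        "n_pos_bins": 2,
        "coupling_mode": "mixed",  # or "type_position"
        "coupling_w_type": 0.3,
        "coupling_w_pos": 0.5,
        "coupling_strength": 0.7,
        "baseline": 1.0,
        "noise_sd": 0.2,
        "drift_sd": 0.01,
        "frame_rate": 5.0,
        "tau": 7.0,
    },
    "scoring": {
        "percentile": 95.0,
        "window_pad": 3.0,
        "pooled_percentile": False,
    },
    "ftype": {
        "k": 5,
        "min_members": 10,
        "supercluster_k": 5,
        "damping": 0.7,
    },
    "layers": {
        "n_layers": 3,
        "n_perm": 100,
    },
    "overlap": {
        "min_size": 10,
        "bandwidth": 0.75,
        "grid_size": 20,
        "n_shuffles": 20,
        "grouping": "within-t-type",
    },
    "classify": {
        "n_repeats": 20,
        "test_frac": 0.1,
        "upsample_to": 1000,
        "standardize_positions": False,
    },
    "match": {
        "jitter_sd": 0.5,
        "mask_radius": 2,
    },
}


class ConfigError(ValueError):
    pass


def validate_config(user: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping")
    merged = copy.deepcopy(DEFAULTS)
    for section, value in user.items():
        if section not in DEFAULTS:
            raise ConfigError(f"unknown config section {section!r}")
        if section == "seed":
            merged["seed"] = int(value)
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, v in value.items():
            if key not in DEFAULTS[section]:
                raise ConfigError(f"unknown key {key!r} in section {section!r}")
            merged[section][key] = v
    return merged


def load_config(path: str | None) -> dict:
    if path is None:
        return validate_config({})
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)
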