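"""Run configuration: defaults, validation, unknown-key rejection.

A run config is a nested mapping with optional stage blocks
(``simulate``, ``behavior``, ``encoding``, ``fluidics``).  Validation
fills assay-protocol defaults (bout thresholds 1.2 deg/ms and 12 um/ms,
1-mm border margin, 4-mm proximity exclusion, 21/9 dF/F frames,
2.5x/1.25x significance factors, 20:1 spillover ratio, 0.5-s motor
bins, 0.65/0.35 bias bounds), rejects unknown keys by name, and demands
an explicit seed for every stochastic stage.
"""

from __future__ import annotations

import copy
from typing import Any

__all__ = ["DEFAULTS", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict[str, Any] = {
    "output_dir": "chemonav_out",
    "seed": None,
    "simulate": {
        "enabled": False,
        "seed": None,
        "behavior": {
            "n_larvae": 3,
            "duration_s": 120.0,
            "fps": 240.0,
            "baseline_bout_rate": 1.0,
            "zone_rate_multiplier": 1.0,
            "turn_angle_sd_baseline": 30.0,
            "turn_angle_sd_zone": 30.0,
            "first_bout_gain": 1.0,
            "linear_speed": 15.0,
        },
        "calcium": {
            "n_rois": 10,
            "regions": ["OB"],
            "w_ipsi": 1.0,
            "w_contra": 0.0,
            "summation": "linear",
            "noise_sd": 0.15,
            "amplitude": 0.4,
            "n_trials": 4,
            "motor_weight": 0.0,
        },
    },
    "behavior": {
        "enabled": False,
        "trajectories": None,
        "fps": 240.0,
        "ang_thresh": 1.2,
        "lin_thresh": 12.0,
        "margin_mm": 1.0,
        "exclusion_mm": 4.0,
        "pixel_mm": 1.0,
        "smooth_frames": 3,
        "merge_gap_ms": 50.0,
        "min_frames": 2,
        "arena_width_mm": 60.0,
        "arena_height_mm": 30.0,
        "border_x_mm": 40.0,
        "mirror_border_x_mm": 20.0,
    },
    "encoding": {
        "enabled": False,
        "h5": None,
        "seed": None,
        "strong_factor": 2.5,
        "moderate_factor": 1.25,
        "shuffles": 1,
        "exclude_frames": 21,
        "baseline_frames": 9,
        "bin_s": 0.5,
        "bias_bound": 0.15,
        "spillover_min_ratio": 20.0,
        "mi_method": "resubstitution",
        "mi_grid": 64,
    },
    "fluidics": {
        "enabled": False,
        "a_mm": 1.5,
        "b_mm": 60.0,
        "q_inlet_ul_min": 220.0,
        "n_inlets": 3,
        "rho": 996.0,
        "mu": 8.32e-4,
        "diffusivity": 0.66e-9,
    },
}

_POSITIVE = {
    ("behavior", "fps"),
    ("behavior", "ang_thresh"),
    ("behavior", "lin_thresh"),
    ("behavior", "pixel_mm"),
    ("encoding", "strong_factor"),
    ("encoding", "moderate_factor"),
    ("fluidics", "a_mm"),
    ("fluidics", "b_mm"),
    ("fluidics", "rho"),
    ("fluidics", "mu"),
    ("fluidics", "diffusivity"),
}
_NON_NEGATIVE = {
    ("behavior", "margin_mm"),
    ("behavior", "exclusion_mm"),
    ("fluidics", "q_inlet_ul_min"),
}


def _merge(defaults: dict, user: dict, path: str) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def validate_config(cfg: dict | None) -> dict:
    """Validate a config mapping against the schema and fill defaults.

    Any stage block present in the input is enabled unless it sets
    ``enabled: false`` explicitly.  Raises ConfigError for unknown keys,
    out-of-range values, or a stochastic stage without a seed.
    """
    cfg = cfg or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    for stage in ("simulate", "behavior", "encoding", "fluidics"):
        block = cfg.get(stage)
        if isinstance(block, dict) and "enabled" not in block:
            block["enabled"] = True
    merged = _merge(DEFAULTS, cfg, "")

    for stage, key in _POSITIVE:
        v = merged[stage][key]
        if not (isinstance(v, (int, float)) and v > 0):
            raise ConfigError(f"{stage}.{key} must be positive, got {v!r}")
    for stage, key in _NON_NEGATIVE:
        v = merged[stage][key]
        if not (isinstance(v, (int, float)) and v >= 0):
            raise ConfigError(f"{stage}.{key} must be non-negative, got {v!r}")

    top_seed = merged["seed"]
    for stage in ("simulate", "encoding"):
        if merged[stage]["enabled"]:
            if merged[stage]["seed"] is None:
                merged[stage]["seed"] = top_seed
            if merged[stage]["seed"] is None:
                raise ConfigError(
                    f"stochastic stage '{stage}' requires a seed "
                    "(set it in the block or at top level)"
                )
    return merged
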