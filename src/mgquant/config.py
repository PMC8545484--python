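"""Declarative run configuration.

A single YAML file configures every stage.  Defaults are materialised into
the resolved config at load time so the manifest records every effective
parameter — no hidden defaults at run time.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised with the dotted path of the offending field."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_traces": 5,
        "trace": {
            "duration_s": 300.0, "frame_rate_hz": 1.0,
            "transient_rate_per_min": 0.13, "amplitude_dff": 0.4,
            "decay_tau_s": 8.0, "rise_s": 1.0, "noise_sd_dff": 0.02,
            "drift_amplitude_dff": 0.0, "drift_period_s": 300.0,
        },
        "puncta": {
            "fov_um": 102.0, "pixel_size_um": 0.1,
            "density_pre_per_100um2": 53.0, "density_post_per_100um2": 42.0,
            "density_coloc_per_100um2": 26.0, "punctum_diameter_um": 0.5,
            "punctum_intensity": 120, "background_level": 5, "noise_sd": 2.0,
        },
        "scene": {
            "n_cells": 12, "frac_phagocytic": 0.5,
            "beads_per_phagocytic_cell": 1, "n_external_beads": 5,
            "fov_um": 106.0, "z_planes": 5, "z_step_um": 2.0,
            "pixel_size_um": 0.5, "cell_radius_um": 8.0,
        },
        "pattern": {
            "mode": "poisson", "intensity_per_um2": 1e-4, "fov_um": 640.0,
            "jitter_sd_um": 0.0,
        },
        "current": {
            "duration_s": 60.0, "sample_rate_hz": 20000.0,
            "event_rate_pre_hz": 2.0, "event_rate_post_hz": 1.0,
            "ttx_onset_s": None, "amplitude_mean_pA": 30.0,
            "amplitude_sd_pA": 5.0, "rise_ms": 0.5, "decay_ms": 5.0,
            "noise_sd_pA": 3.0, "holding_pA": -100.0,
            "agonist_step_pA": 0.0, "agonist_onset_s": None,
        },
    },
    "calcium": {
        "input": "traces.csv",
        "lesion_frame": None,
        "params": {
            "smoothing_frames": 100, "threshold_multiplier": 2.25,
            "baseline_eligibility_dff": 0.1, "min_area_dff_s": 0.15,
            "n_baseline_points": 100, "merge_gap_frames": 2,
        },
    },
    "puncta": {
        "pre_image": "puncta_pre.tif",
        "post_image": "puncta_post.tif",
        "pixel_size_um": 0.1,
        "pre_threshold": [15, 255],
        "post_threshold": [30, 255],
        "background_radius_px": 10,
    },
    "phago": {
        "masks": "scene_masks.tif",
        "beads": "beads.csv",
        "pixel_size_um": 0.5,
        "z_step_um": 2.0,
        "min_beads": 1,
    },
    "spatial": {
        "input": "somata.csv",
        "fov_um": 640.0,
        "toroidal": False,
    },
    "ephys": {
        "input": "current.csv",
        "threshold_pA": 15.0,
        "min_interval_ms": 5.0,
        "ttx_onset_s": None,
        "agonist_onset_s": None,
        "temperature_C": 33.0,
    },
    "aggregate": {
        "input": "per_image.csv",
        "hierarchy": ["animal", "slice"],
    },
}

# fields that must not resolve to None (a stage cannot run without them)
_REQUIRED = [
    ("puncta", "pixel_size_um"),
    ("phago", "pixel_size_um"),
    ("spatial", "fov_um"),
    ("ephys", "threshold_pA"),
]


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value, f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(value)
    return out


def resolve_config(source: str | Path | dict | None = None) -> dict[str, Any]:
    """Merge user config over defaults and validate required fields."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    config = _deep_merge(DEFAULT_CONFIG, user)
    for stage, field in _REQUIRED:
        if config.get(stage, {}).get(field) is None:
            raise ConfigError(f"{stage}.{field} is required but unset")
    return config
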