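"""Run configuration: a validated, fully-defaulted parameter tree.

The config is a YAML mapping with a fixed schema; unknown keys anywhere in
the tree are rejected before anything runs.  Every parameter has the
documented default, so an empty file (or ``RunConfig()``) describes the
standard pure-simulation demo run.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

ALL_STAGES = ("simulate", "clocks", "transcript", "rejuvenation", "memory", "phenotype")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "rejuvkit_run",
    "log_level": "INFO",
    "stages": list(ALL_STAGES),
    "cohort": {
        "n_samples": 200,
        "age_range": [1.0, 94.0],
        "n_cpgs": 2000,
        "n_aging_cpgs": 500,
        "aging_slope_range": [0.001, 0.004],
        "baseline_range": [0.05, 0.95],
        "noise_sd": 0.03,
    },
    "expression": {
        "n_genes": 1200,
        "n_aging_genes": 300,
        "ramp_fraction": 0.5,
        "noise_sd": 0.3,
    },
    "course": {
        "groups": {"negative_control": 0.0, "failed": 10.0, "transient": 30.0,
                   "complete": 38.0},
        "timepoints": ["day0", "day13", "day50"],
        "n_donors": 6,
        "donor_age_range": [38.0, 53.0],
        "archetype_props": [0.67, 0.23, 0.10],
        "n_identity_genes": 300,
    },
    "clocks": {"l1_ratio": 0.5, "cv_folds": 5},
    "transcript": {"kind": "binarized_linear", "cv_folds": 10, "cv_repeats": 3,
                   "alpha": 0.05},
    "rejuvenation": {"threshold_per_40y": 0.10, "reversal_min": 0.0,
                     "max_gap": 1000, "min_sites": 2,
                     "effect_min": 0.5, "alpha": 0.05},
    "memory": {"lfc_min": 2.0, "alpha": 0.05, "k": 3,
               "promoter_window": 1000, "enhancer_window": 1000000,
               "gain_min": 0.2},
    "phenotype": {
        "wound_speeds": [2.0, 5.0, 10.0, 20.0],
        "wound_noise": 0.01,
        "pixel_size": 1.0,
        "frame_interval": 0.3333333333333333,
        "n_frames": 31,
        "n_cells": 8,
        "coverage_min": 0.5,
    },
}


def _merge_checked(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and key != "groups":
            if not isinstance(value, dict):
                raise ConfigurationError(f"{here} must be a mapping")
            out[key] = _merge_checked(defaults[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration with all defaults applied."""

    params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_mapping(cls, user: dict | None) -> "RunConfig":
        cfg = cls(_merge_checked(DEFAULTS, user or {}))
        unknown = set(cfg.params["stages"]) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_mapping(user)

    def __getitem__(self, key):
        return self.params[key]

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.params["outdir"])

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.params, sort_keys=True).encode()
        ).hexdigest()
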