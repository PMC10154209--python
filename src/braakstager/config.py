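"""Run configuration: embedded defaults, YAML overrides, CLI precedence.

Precedence is CLI flag > config file > embedded default; the resolved
configuration is written alongside every run's outputs for provenance.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Optional

import yaml

DEFAULTS: dict = {
    "seed": 1,
    "k_sd": 2.5,
    "pet_threshold": 1.55,
    "csf_ratio_threshold": 0.068,
    # no validated temporal meta-ROI cutoff is bundled; users must supply one
    "meta_roi_threshold": None,
    "loess_span": 0.75,
    "dunnett_draws": 50_000,
    "alpha": 0.05,
    "n_permutations": 5_000,
    "gate_stage": 3,
    # orientation registry: biomarkers whose low values are abnormal get
    # sign-flipped before 0-10 scaling; everything else is higher-is-abnormal
    "orientation_lower_is_abnormal": [
        "csf_ab42",
        "csf_ab42_ab40_ratio",
        "hippocampal_volume_adj",
        "mmse",
        "moca",
        "memory",
        "executive",
        "language",
        "visuospatial",
    ],
    # stage pairs for the amyloid positivity-proportion chi-square tests
    "proportion_stage_pairs": [[0, 1], [0, 2], [2, 3], [4, 5], [4, 6], [5, 6]],
    "trajectory_biomarkers": [
        "suvr_amyloid",
        "csf_ab42_ab40_ratio",
        "csf_ptau181",
        "csf_ptau217",
        "csf_ptau231",
        "csf_ptau235",
        "plasma_ptau181",
        "plasma_ptau231",
        "plasma_nfl",
        "csf_neurogranin",
        "csf_snap25",
        "hippocampal_volume_adj",
        "mmse",
    ],
    # overrides forwarded to synthetic.GeneratorConfig
    "generator": {},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    """Resolve the configuration: defaults <- YAML file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, {k: v for k, v in overrides.items() if v is not None})
    return cfg


def dump_config(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
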