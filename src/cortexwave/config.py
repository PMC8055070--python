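"""Pipeline configuration: nested defaults, strict key validation, YAML IO."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

__all__ = ["default_config", "load_config", "merge_config", "validate_config"]


def default_config() -> Dict[str, Any]:
    return {
        "seed": 0,
        "version": "0.1.0",
        "simulate": {
            "shape": [900, 44, 52],
            "frame_rate": 150.0,
            "noise_sd": 0.2,
            "components": [
                {"kind": "plane", "freq_hz": 2.0, "wavevector": [0.2, 0.1],
                 "amplitude": 1.0},
            ],
        },
        "band": {"low": 0.5, "high": 4.0},
        "cheby": {"attenuation_db": 40.0},
        "artifact": {"k_sd": 3.0, "guard_s": 0.5},
        "coarse": {"enabled": False, "scale": 0.5},
        "flow": {"alpha": 0.5, "penalty": "charbonnier", "charbonnier_eps": 1e-3,
                 "max_iters": 1000, "tol": 1e-6, "sor_omega": 1.9, "n_scales": 3},
        "patterns": {"plane_thresh": 0.85, "standing_k": 2.0, "link_tol": 2.0,
                     "ring_agreement": 0.8, "d": 5, "r": 3},
        "modes": {"k": 20},
        "stats": {"op_thresh": 0.5, "box_fraction": 0.3, "n_perm": 1000},
    }


def validate_config(cfg: Dict[str, Any], reference: Optional[Dict[str, Any]] = None,
                    path: str = "") -> None:
    """Reject keys absent from the default schema, naming the offender."""
    if reference is None:
        reference = default_config()
    for key, value in cfg.items():
        if key not in reference:
            where = f"{path}.{key}" if path else key
            raise KeyError(f"unknown config key: {where}")
        if isinstance(value, dict) and isinstance(reference[key], dict):
            # 'components' entries are free-form specs, not schema nodes
            validate_config(value, reference[key], f"{path}.{key}" if path else key)


def merge_config(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: Optional[Dict[str, Any]] = None,
                ) -> Dict[str, Any]:
    """Fully resolved configuration: defaults <- file <- overrides."""
    cfg = default_config()
    if path is not None:
        with open(Path(path)) as f:
            user = yaml.safe_load(f) or {}
        validate_config(user)
        cfg = merge_config(cfg, user)
    if overrides:
        validate_config(overrides)
        cfg = merge_config(cfg, overrides)
    return cfg
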