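"""Default numeric configuration and YAML overrides.

A single nested mapping holds every tunable the pipeline uses; a YAML
file with the same hierarchy deep-merges over the defaults, and CLI
flags mirror the dotted key paths.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULTS", "load_config", "get_key"]

DEFAULTS: dict[str, Any] = {
    "preprocess": {
        "lowpass_order": 8,
        "lowpass_cutoff_hz": 20.0,
        "resample_dt_s": 0.2,  # 5 Hz product for transfer function analysis
        "model_dt_s": 0.5,  # 2 Hz product for the SVR models
        "poly_order": 3,
    },
    "tfa": {
        "seg_len": 512,
        "overlap": 0.5,
        "window": "hann",
        "alpha": 0.05,
    },
    "tiecks": {
        "pre_s": 30.0,
        "post_s": 20.0,
        "amplitude_frac": 0.10,
        "grid_step": 0.1,
        "crcp_mmhg": 12.0,
    },
    "mfari": {
        "min_tau_s": 1.0,
        "max_tau_s": 15.0,
        "phi_mode": "flat_bp",  # or "fitted_bp"
    },
    "svm": {
        "grid": "reduced",  # "reduced" | "default" | explicit mapping
        "settle_s": 60.0,
        "step_amplitude": 0.2,
        "post_s": 20.0,
    },
    "roc": {"n_boot": 5000},
    "synthetic": {
        "duration_s": 300.0,
        "rate_hz": 5.0,
        "bp_mean_mmhg": 94.5,
        "bp_sd_mmhg": 5.0,
        "cbfv_base_cm_s": 57.4,
        "noise_sd_frac": 0.05,
    },
}


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """The defaults, optionally overridden by a YAML file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is None:
        return cfg
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return _merge(cfg, loaded)


def get_key(cfg: dict, dotted: str) -> Any:
    """Fetch ``cfg['a']['b']`` via ``"a.b"``."""
    node = cfg
    for part in dotted.split("."):
        node = node[part]
    return node
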