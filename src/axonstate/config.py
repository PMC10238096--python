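"""Pipeline configuration: defaults mirroring the standard analysis parameters.

The default configuration encodes the canonical analysis settings
(walk threshold 2.5 cm/s for >= 2 s, whisk threshold 20% of normalized
whisker MEI for > 1 s, twitch < 0.5 s, 1 s stillness gate, trace SNR
criterion log(20), coherence with 2 min windows at 98% overlap, 3 s
cross-correlation lag, 1 Hz analysis low-pass), so running the pipeline
without a config file reproduces the standard analysis.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

DEFAULT_CONFIG: dict = {
    "stages": ["simulate", "detect", "preprocess", "align", "spectral",
               "encode", "decompose"],
    "simulate": {
        "duration_s": 600.0,
        "frame_rate_hz": 15.0,
        "video_rate_hz": 30.0,
        "n_axons": 12,
        "n_rois": 4,
        "common_gain": 1.0,
        "private_sd": 0.5,
        "noise_sd": 0.05,
        "n_same_axon_pairs": 2,
        "n_blebs": 2,
        "n_mcherry": 0,
    },
    "detect": {
        "whisk_thresh": 0.20,
        "walk_speed": 2.5,
        "walk_min_s": 2.0,
        "whisk_min_s": 1.0,
        "twitch_max_s": 0.5,
        "still_gap_s": 1.0,
        "strict": False,
    },
    "preprocess": {
        "fs_out": 100.0,
        "lp_hz": 10.0,
        "snr_threshold": "log20",
        "log_scale": True,
    },
    "align": {
        "window_pre_s": 2.0,
        "window_post_s": 5.0,
        "alpha": 0.01,
        "n_shuffles": 200,
    },
    "spectral": {
        "window_s": 120.0,
        "overlap": 0.98,
        "xcorr_max_lag_s": 3.0,
        "lowpass_hz": 1.0,
    },
    "encode": {
        "k_folds": 5,
        "lowpass_hz": 1.0,
        "fit_fs": 10.0,
    },
    "decompose": {
        "lowpass_hz": 1.0,
        "modes": ["full", "stationary", "still"],
        "min_duration_s": 60.0,
    },
}


def resolve_threshold(value) -> float:
    """Resolve 'logN' strings (e.g. 'log20') or numbers to a float threshold."""
    if isinstance(value, str):
        if value.startswith("log"):
            return float(np.log(float(value[3:])))
        return float(value)
    return float(value)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | dict | None = None) -> dict:
    """Load a YAML config merged over the defaults; None gives the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(path, dict):
        return _merge(DEFAULT_CONFIG, path)
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    return _merge(DEFAULT_CONFIG, user)
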