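"""Structured YAML configuration with schema validation.

A config file overrides any subset of the defaults below; unknown keys
are rejected so typos surface immediately.  The merged "effective config"
is logged at load time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

logger = logging.getLogger("genarch")

DEFAULTS: dict = {
    "priors": {
        "ne": [5e4, 2e6],
        "t_recent": [5e4, 5e5],
        "t_deep": [5e4, 2e6],
        "mig": [0.0, 4.0],
    },
    "mu": 2.42e-9,
    "r_max": 3.021e-9,  # upper bound of the intralocus recombination prior
    "gen_time": 1.0,
    "t_outgroup": 9.6e6,
    "window_size": 100_000,
    "min_sites": 500,
    "snps_per_window": 1000,
    "max_missing": 0.3,
    "class_threshold": 0.7,
    "quantile_fraction": 0.1,
    "ld_r2": 0.2,
}

_SCHEMA = {
    "priors": dict,
    "mu": (int, float),
    "r_max": (int, float),
    "gen_time": (int, float),
    "t_outgroup": (int, float),
    "window_size": int,
    "min_sites": int,
    "snps_per_window": int,
    "max_missing": (int, float),
    "class_threshold": (int, float),
    "quantile_fraction": (int, float),
    "ld_r2": (int, float),
}


def load_config(path: str | Path | None = None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if key not in _SCHEMA:
                raise ValueError(f"unknown config key {key!r}")
            if not isinstance(val, _SCHEMA[key]):
                raise ValueError(f"config key {key!r}: expected {_SCHEMA[key]}")
            if key == "priors":
                for pk, bounds in val.items():
                    if pk not in cfg["priors"]:
                        raise ValueError(f"unknown prior {pk!r}")
                    lo, hi = float(bounds[0]), float(bounds[1])
                    if lo > hi:
                        raise ValueError(f"prior {pk!r}: lo > hi")
                    cfg["priors"][pk] = [lo, hi]
            else:
                cfg[key] = val
    logger.info("effective config: %s", cfg)
    return cfg
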