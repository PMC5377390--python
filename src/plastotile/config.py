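"""YAML configuration for the command-line pipeline.

A config file holds nested sections mirroring the pipeline stages; every key
is optional and falls back to the package default.  Example::

    simulate:
      genome_length: 40000
      seed: 10
    design:
      probe_length: 35
      step: 5
      n_negative_controls: 54
      replicate_fraction: 0.67
    normalize:
      nc_sd_multiplier: 2.0
      qc_min_pearson: 0.99
      qc_max_cv: 0.20
      threshold_pool: global
    segment:
      bandwidth: 150
      join_factor: 3
      min_length_factor: 5
    diff:
      alpha: 0.05
      min_coverage: 0.5
      min_effect: 0.2
    promoter:
      window: 100
      max_mismatch: 1
      gap_range: [4, 12]
      spacer_range: [15, 21]
      gaa_range: [10, 40]
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULTS: dict = {
    "simulate": {"genome_length": 40000, "seed": 10},
    "design": {
        "probe_length": 35,
        "step": 5,
        "n_negative_controls": 54,
        "replicate_fraction": 0.67,
    },
    "normalize": {
        "nc_sd_multiplier": 2.0,
        "qc_min_pearson": 0.99,
        "qc_max_cv": 0.20,
        "threshold_pool": "global",
    },
    "segment": {"bandwidth": 150.0, "join_factor": 3, "min_length_factor": 5},
    "diff": {"alpha": 0.05, "min_coverage": 0.5, "min_effect": 0.2},
    "promoter": {
        "window": 100,
        "max_mismatch": 1,
        "gap_range": [4, 12],
        "spacer_range": [15, 21],
        "gaa_range": [10, 40],
        "min_shift": 25,
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Deep-merge a YAML config file over the package defaults."""
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        cfg.setdefault(section, {}).update(values)
    return cfg
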