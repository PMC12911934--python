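"""YAML run configuration with defaults and CLI overrides."""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from magfred.exceptions import ValidationError

DEFAULTS: dict[str, Any] = {
    "min_completeness": 70.0,
    "max_contamination": 5.0,
    "min_abundance": 0.0,
    "seed": 0,
    "n_permutations": 999,
    "collinearity_threshold": 0.9,
    "scale_per_sample": False,
    "trait_values_for_fred": "raw",  # "raw" hit counts or completeness-"normalized"
    "log2fc_transform": "log2_ratio",
    "expressed_weight": "abundance",
    "expressed_log1p": False,
    "min_expressed_genes": 0,
    "subsets_file": None,  # None -> packaged defaults
}


def load_config(path: str | Path | None = None, **overrides: Any) -> dict[str, Any]:
    """Merge defaults, an optional YAML file, and keyword overrides (in that order)."""
    config = dict(DEFAULTS)
    if path is not None:
        with open(path, "r", encoding="utf-8") as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config {path} must be a YAML mapping")
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config keys in {path}: {sorted(unknown)}")
        config.update(loaded)
    config.update({k: v for k, v in overrides.items() if v is not None})
    return config
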