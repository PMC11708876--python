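"""Flat key-value configuration with a single schema validator.

Every analysis threshold is a config key so the filters applied at each
stage are auditable; the defaults are the study's published choices where
one exists (selection-rule P-value cutoffs, the 90-nt start window, the
19-32 nt footprint range, five guides per target, the cap of 3 on the GSEA
ranking multiplier) and documented package choices elsewhere.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

#: key -> (type, default); ``REQUIRED`` marks keys without defaults.
REQUIRED = object()

SCHEMA: dict[str, tuple[type, Any]] = {
    "seed": (int, REQUIRED),
    "out_dir": (str, REQUIRED),
    # inputs (optional: stages may be given frames directly)
    "annotation": (str, None),
    "alignments": (str, None),
    "rna_counts": (str, None),
    "sample_sheet": (str, None),
    "gene_sets": (str, None),
    "guide_pools": (str, None),
    "screen_counts": (str, None),
    "screen_sample_sheet": (str, None),
    "library": (str, None),
    # quantification
    "psite_offset": (int, 12),
    "footprint_min_len": (int, 19),
    "footprint_max_len": (int, 32),
    "start_window_nt": (int, 90),
    "s2b_min_rpf": (int, 32),
    "s2b_min_cds_len": (int, 100),
    "s2b_multiplier": (str, "length_minus_90"),   # or "length_ratio"
    # differential testing
    "min_mean_count": (float, 5.0),
    "dispersion_prior_sd": (float, 0.5),
    # GSEA
    "gsea_cap": (float, 3.0),
    "gsea_weight": (float, 1.0),
    "gsea_n_perm": (int, 1000),
    "gsea_min_set": (int, 5),
    "gsea_max_set": (int, 500),
    # library design selection rules
    "te_adjp_max": (float, 0.1),
    "s2b_p_max": (float, 0.1),
    "s2b_use_adjusted_p": (bool, False),
    "ro_adjp_max": (float, 0.05),
    "rna_adjp_min": (float, 0.05),
    "uorf_adjp_max": (float, 0.05),
    "n_guides_per_region": (int, 5),
    "n_nontargeting": (int, 100),
    "flank5": (str, "GGAAAGGCGTCTCACACCG"),
    "flank3": (str, "GTTTTAGAGACGTTTTT"),
    # screen scoring
    "screen_pseudocount": (float, 1.0),
    "screen_n_resamples": (int, 10000),
    "screen_fdr": (float, 0.05),
}


class ConfigError(ValueError):
    pass


def validate_config(raw: dict[str, Any]) -> dict[str, Any]:
    """Validate a flat mapping against the schema, filling defaults."""
    unknown = set(raw) - set(SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    out: dict[str, Any] = {}
    missing: list[str] = []
    for key, (typ, default) in SCHEMA.items():
        if key in raw and raw[key] is not None:
            val = raw[key]
            if typ is float and isinstance(val, int):
                val = float(val)
            if typ is int and isinstance(val, bool):
                raise ConfigError(f"config key {key}: expected int, got bool")
            if not isinstance(val, typ):
                raise ConfigError(
                    f"config key {key}: expected {typ.__name__}, got {type(val).__name__}")
            out[key] = val
        elif default is REQUIRED:
            missing.append(key)
        else:
            out[key] = default
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    return validate_config(raw)


def default_config(seed: int, out_dir: str, **overrides: Any) -> dict[str, Any]:
    return validate_config({"seed": seed, "out_dir": out_dir, **overrides})
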