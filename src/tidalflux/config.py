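"""Declarative run configuration: defaults, validation, loading."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["default_config", "validate_config", "load_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "site": {"lat": 44.9, "lon": -67.0, "utc_offset": -4.0},
    "thresholds": {"ts_threshold_db": -50.0, "min_targets": 5},
    "gapfill": {
        "method": "harmonic",
        "max_periods": 6,
        "noise": True,
        "min_window_hours": 48.0,
        "max_period_rule": "total",
        "periods": "auto",
    },
    "wavelet": {
        "omega0": 6.0,
        "voices_per_octave": 16,
        "n_sim": 100,
        "alpha": 0.05,
        "min_period": 2.0,
        "max_period": None,
    },
    "tide": {
        "constituents": "all",
        "seam": 20.0,
        "slack_halfwidth_minutes": 30.0,
        "rising_is_low": True,
    },
    "patterns": {"crepuscular_halfwidth_hours": 1.5},
    "seeds": {"gapfill": 0, "wavelet": 0, "simulate": 0},
    "paths": {"counts": None, "tracks": None, "directions": None, "out_dir": "tidalflux_out"},
    "simulate": None,
}

_RANGES = {
    ("site", "lat"): ((int, float), lambda v: -66 < v < 66, "within (-66, 66) degrees"),
    ("site", "lon"): ((int, float), lambda v: -180 <= v <= 180, "within [-180, 180] degrees"),
    ("site", "utc_offset"): ((int, float), lambda v: -14 <= v <= 14, "within [-14, 14] hours"),
    ("thresholds", "ts_threshold_db"): ((int, float), lambda v: True, ""),
    ("thresholds", "min_targets"): ((int,), lambda v: v >= 1, ">= 1"),
    ("gapfill", "method"): (
        (str,),
        lambda v: v in ("harmonic", "median", "linear"),
        "one of harmonic|median|linear",
    ),
    ("gapfill", "max_periods"): ((int,), lambda v: v >= 1, ">= 1"),
    ("gapfill", "noise"): ((bool,), lambda v: True, ""),
    ("gapfill", "min_window_hours"): ((int, float), lambda v: v > 0, "> 0"),
    ("gapfill", "max_period_rule"): (
        (str,),
        lambda v: v in ("total", "per_side"),
        "one of total|per_side",
    ),
    ("wavelet", "omega0"): ((int, float), lambda v: v >= 5, ">= 5"),
    ("wavelet", "voices_per_octave"): ((int,), lambda v: v >= 1, ">= 1"),
    ("wavelet", "n_sim"): ((int,), lambda v: v >= 1, ">= 1"),
    ("wavelet", "alpha"): ((int, float), lambda v: 0 < v < 1, "within (0, 1)"),
    ("wavelet", "min_period"): ((int, float), lambda v: v > 0, "> 0"),
    ("tide", "seam"): ((int, float), lambda v: 0 <= v < 360, "within [0, 360)"),
    ("tide", "slack_halfwidth_minutes"): ((int, float), lambda v: v >= 0, ">= 0"),
    ("tide", "rising_is_low"): ((bool,), lambda v: True, ""),
    ("patterns", "crepuscular_halfwidth_hours"): ((int, float), lambda v: v >= 0, ">= 0"),
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def merge_config(overrides: dict | None) -> dict:
    """Defaults overlaid with a (possibly partial) user mapping."""
    cfg = default_config()
    for section, content in (overrides or {}).items():
        if section in cfg and isinstance(cfg[section], dict) and isinstance(content, dict):
            cfg[section].update(content)
        else:
            cfg[section] = content
    return cfg


def validate_config(config: dict) -> list[str]:
    """All violations in a configuration mapping, without side effects."""
    violations: list[str] = []
    for section in config:
        if section not in DEFAULT_CONFIG:
            violations.append(f"unknown section: {section}")
    for section, defaults in DEFAULT_CONFIG.items():
        got = config.get(section)
        if got is None or not isinstance(defaults, dict):
            continue
        if not isinstance(got, dict):
            violations.append(f"section {section} must be a mapping")
            continue
        for key in got:
            if key not in defaults:
                violations.append(f"unknown key: {section}.{key}")
        for (sec, key), (types, ok, legal) in _RANGES.items():
            if sec != section or key not in got:
                continue
            v = got[key]
            if isinstance(v, bool) and bool not in types:
                violations.append(f"{sec}.{key} must be of type {types[0].__name__}")
            elif not isinstance(v, types):
                violations.append(
                    f"{sec}.{key} must be of type {'/'.join(t.__name__ for t in types)}, "
                    f"got {type(v).__name__}"
                )
            elif not ok(v):
                violations.append(f"{sec}.{key} must be {legal}, got {v}")
    seeds = config.get("seeds") or {}
    if isinstance(seeds, dict):
        for k, v in seeds.items():
            if not isinstance(v, int) or isinstance(v, bool):
                violations.append(f"seeds.{k} must be an integer")
    tide = config.get("tide") or {}
    cons = tide.get("constituents") if isinstance(tide, dict) else None
    if cons is not None and cons != "all" and not isinstance(cons, (list, tuple)):
        violations.append("tide.constituents must be 'all' or a list of names")
    paths = config.get("paths") or {}
    if isinstance(paths, dict):
        for k in ("counts", "tracks", "directions"):
            p = paths.get(k)
            if p is not None and not Path(p).exists():
                violations.append(f"paths.{k} does not exist: {p}")
    return violations


def load_config(path) -> dict:
    """Parse a YAML configuration document and merge it over the defaults."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"unparseable configuration {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"configuration root must be a mapping in {path}")
    return merge_config(doc)
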