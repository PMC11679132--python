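"""Run configuration: factor tables and landmark conventions.

A config file is a single YAML (or JSON) mapping; every key is optional and
defaults to the shipped ICRP tables and conventions::

    conversion_factors:        # mSv/(mGy*cm) per region
      head: 0.0021
      neck: 0.0059
      chest: 0.014
      abdomen: 0.015
      pelvis: 0.015
      femur: 0.015
    weighting_factors:         # mSv/MBq by closed age band; max null = open
      - {min: 0, max: 1, factor: 0.095}
      - {min: 2, max: 5, factor: 0.056}
      - {min: 6, max: 10, factor: 0.037}
      - {min: 11, max: 15, factor: 0.024}
      - {min: 16, max: null, factor: 0.019}
    boundary_rule: superior    # C1/T1 boundary slice: superior|inferior|centroid
    head_margin_warning: 10    # warn when > this many slices sit above the skull top
    segment_command: null      # optional external segmentation hook, off by default
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .dosimetry import ConversionFactorTable, WeightingFactorTable
from .errors import ConfigurationError


@dataclass(frozen=True)
class PipelineConfig:
    conversion_factors: ConversionFactorTable = field(
        default_factory=ConversionFactorTable.icrp102
    )
    weighting_factors: WeightingFactorTable = field(
        default_factory=WeightingFactorTable.icrp128_fdg
    )
    boundary_rule: str = "superior"
    head_margin_warning: int = 10
    #: shell template run when a study lacks masks, e.g.
    #: "TotalSegmentator -i {ct} -o {out}"; None disables the hook
    segment_command: str | None = None


def load_conversion_factors(path: str | Path) -> ConversionFactorTable:
    """Region -> factor mapping from a YAML/JSON file."""
    raw = _load_yaml(path)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} must hold a region->factor mapping")
    return ConversionFactorTable({str(k): float(v) for k, v in raw.items()})


def _parse_weighting(raw) -> WeightingFactorTable:
    try:
        bands = tuple(
            (int(b["min"]), None if b.get("max") is None else int(b["max"]), float(b["factor"]))
            for b in raw
        )
    except (TypeError, KeyError) as exc:
        raise ConfigurationError(
            f"weighting_factors entries need min/max/factor keys: {exc}"
        ) from exc
    return WeightingFactorTable(bands)


def _load_yaml(path: str | Path):
    try:
        with open(path) as fh:
            return yaml.safe_load(fh)
    except Exception as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, overriding defaults from a file."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = _load_yaml(path)
    if raw is None:
        return cfg
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    known = {
        "conversion_factors", "weighting_factors", "boundary_rule",
        "head_margin_warning", "segment_command",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    updates: dict = {}
    if "conversion_factors" in raw:
        updates["conversion_factors"] = ConversionFactorTable(
            {str(k): float(v) for k, v in raw["conversion_factors"].items()}
        )
    if "weighting_factors" in raw:
        updates["weighting_factors"] = _parse_weighting(raw["weighting_factors"])
    if "boundary_rule" in raw:
        updates["boundary_rule"] = str(raw["boundary_rule"])
    if "head_margin_warning" in raw:
        updates["head_margin_warning"] = int(raw["head_margin_warning"])
    if "segment_command" in raw:
        updates["segment_command"] = raw["segment_command"]
    return replace(cfg, **updates)
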