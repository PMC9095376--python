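"""YAML pipeline configuration.

One document with optional ``vesselness``, ``grow`` and ``seeding``
sections mapping onto :class:`~ctaseg.vesselness.VesselnessParams`,
:class:`~ctaseg.segmentation.GrowConfig` and
:class:`~ctaseg.seeding.SeedingConfig`, plus top-level ``log_level``.
Unknown keys are rejected so typos fail loudly instead of silently
running defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .seeding import SeedingConfig
from .segmentation import GrowConfig
from .vesselness import VesselnessParams


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


@dataclass
class PipelineConfig:
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    grow: GrowConfig = field(default_factory=GrowConfig)
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    log_level: str = "INFO"


_SECTIONS = {
    "vesselness": VesselnessParams,
    "grow": GrowConfig,
    "seeding": SeedingConfig,
}


def _build_section(cls, payload: dict, section: str):
    if not isinstance(payload, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}; "
                          f"allowed: {sorted(known)}")
    coerced = dict(payload)
    for key in ("scales", "radius_range"):
        if key in coerced and coerced[key] is not None:
            coerced[key] = tuple(coerced[key])
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' configuration: {exc}") from exc


def load_config(path: str) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"log_level"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}; "
                          f"allowed: {sorted(_SECTIONS) + ['log_level']}")
    kwargs = {name: _build_section(cls, raw[name], name)
              for name, cls in _SECTIONS.items() if name in raw}
    if "log_level" in raw:
        kwargs["log_level"] = str(raw["log_level"])
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str) -> None:
    """Serialise a pipeline configuration back to YAML."""
    doc = {
        "vesselness": dataclasses.asdict(config.vesselness),
        "grow": dataclasses.asdict(config.grow),
        "seeding": dataclasses.asdict(config.seeding),
        "log_level": config.log_level,
    }
    doc["vesselness"]["scales"] = list(config.vesselness.scales)
    doc["seeding"]["radius_range"] = list(config.seeding.radius_range)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
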