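"""YAML-driven run configuration for the end-to-end pipeline.

A run config bundles the generator, extraction, model and protocol settings
with a root seed.  ``validate_config`` schema-checks a YAML file, fills
defaults, and reports every offending key on failure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import GeneratorConfig
from .features import ExtractionConfig
from .selection import ModelSpec, Protocol


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    protocol: Protocol = field(default_factory=Protocol)
    compact_traces: bool = False  # use the reduced trace geometry
    write_traces: bool = False
    met: float = 1.0
    clo: float = 0.5
    n_comparison_trials: int = 3


class ConfigError(ValueError):
    """Human-readable listing of configuration problems."""


def _build_section(cls, data: dict, section: str, errors: list):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        errors.append(f"{section}: unknown keys {sorted(unknown)} (allowed: {sorted(known)})")
        data = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def validate_config(path_or_dict) -> RunConfig:
    """Load, schema-check and default-fill a run configuration.

    Accepts a YAML file path or an already-parsed mapping.  A minimal config
    (just a seed) expands to the full study defaults: 20 subjects across the
    8-setting factorial, GPR backend, 1.0 met and 0.5 clo for the PMV
    baseline.
    """
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text(encoding="utf-8")) or {}
    else:
        raw = dict(path_or_dict or {})
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    errors: list = []
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_known
    if unknown:
        errors.append(f"top level: unknown keys {sorted(unknown)} (allowed: {sorted(top_known)})")

    sections = {
        "generator": GeneratorConfig,
        "extraction": ExtractionConfig,
        "protocol": Protocol,
        "model": ModelSpec,
    }
    kwargs = {}
    compact = bool(raw.get("compact_traces", False))
    for name, cls in sections.items():
        data = raw.get(name, {}) or {}
        if not isinstance(data, dict):
            errors.append(f"{name}: must be a mapping")
            continue
        if name == "generator" and compact:
            obj = None
            try:
                obj = GeneratorConfig.compact(**{
                    k: v for k, v in data.items()
                    if k in {f.name for f in dataclasses.fields(GeneratorConfig)}
                })
            except (ValueError, TypeError) as exc:
                errors.append(f"generator: {exc}")
            bad = set(data) - {f.name for f in dataclasses.fields(GeneratorConfig)}
            if bad:
                errors.append(f"generator: unknown keys {sorted(bad)}")
            kwargs[name] = obj
        else:
            kwargs[name] = _build_section(cls, data, name, errors)

    for scalar, caster in (
        ("seed", int), ("out_dir", str), ("met", float), ("clo", float),
        ("n_comparison_trials", int), ("write_traces", bool), ("compact_traces", bool),
    ):
        if scalar in raw:
            try:
                kwargs[scalar] = caster(raw[scalar])
            except (ValueError, TypeError):
                errors.append(f"{scalar}: cannot interpret {raw[scalar]!r} as {caster.__name__}")

    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(**kwargs)
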