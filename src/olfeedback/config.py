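"""Configuration loading, validation and round-tripping.

Configs are YAML (or TOML) mappings with one block per tier, using the
field names of the corresponding dataclasses.  Validation is eager: unknown
keys are rejected by name, and every constructed object runs its own
invariant checks (which raise :class:`ValidationError` naming the violated
constraint).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .analytic import FeedbackSpec, OdorPairCounts, ThresholdSpec
from .errors import ValidationError
from .geometry import LayoutSpec
from .population import PopulationSpec
from .rates import DistributionSet, ReadoutSpec
from .spiking import StimulusProgram, SynapseParams

_BLOCKS = {
    "thresholds": ThresholdSpec,
    "feedback": FeedbackSpec,
    "counts": OdorPairCounts,
    "population": PopulationSpec,
    "layout": LayoutSpec,
    "synapses": SynapseParams,
    "stimulus": StimulusProgram,
    "distributions": DistributionSet,
    "readout": ReadoutSpec,
}

_SCALAR_KEYS = {"tier", "seed", "out"}


@dataclass
class RunConfig:
    """A validated run configuration: tier selector, seed and spec blocks."""

    tier: str = "analytic"
    seed: int = 0
    out: str | None = None
    blocks: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Any:
        return self.blocks[name]

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"tier": self.tier, "seed": self.seed}
        if self.out is not None:
            out["out"] = self.out
        for name, obj in self.blocks.items():
            d = dataclasses.asdict(obj)
            # drop nested dataclasses that round-trip via their own block
            if name == "population" and d.get("thresholds") is not None:
                d["thresholds"] = dataclasses.asdict(obj.thresholds)
            out[name] = _plainify(d)
        return out


def _plainify(value: Any) -> Any:
    if isinstance(value, dict):
        return {k: _plainify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plainify(v) for v in value]
    if hasattr(value, "item"):  # numpy scalar
        return value.item()
    return value


def _coerce_block(name: str, cls: type, data: dict) -> Any:
    if not isinstance(data, dict):
        raise ValidationError(f"config block {name!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}; "
            f"allowed: {sorted(fields)}"
        )
    kwargs = dict(data)
    # nested / tuple-typed fields
    for key, val in list(kwargs.items()):
        if isinstance(val, list):
            kwargs[key] = tuple(val)
    if name == "population" and isinstance(kwargs.get("thresholds"), dict):
        kwargs["thresholds"] = _coerce_block("thresholds", ThresholdSpec,
                                             kwargs["thresholds"])
    return cls(**kwargs)


def parse_config(data: dict) -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig` (eagerly)."""
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(data) - set(_BLOCKS) - _SCALAR_KEYS
    if unknown:
        raise ValidationError(
            f"unknown top-level config key(s) {sorted(unknown)}; "
            f"allowed: {sorted(set(_BLOCKS) | _SCALAR_KEYS)}"
        )
    cfg = RunConfig(
        tier=str(data.get("tier", "analytic")),
        seed=int(data.get("seed", 0)),
        out=data.get("out"),
    )
    for name, cls in _BLOCKS.items():
        if name in data:
            cfg.blocks[name] = _coerce_block(name, cls, data[name])
    return cfg


def load_and_validate(path: str | Path) -> RunConfig:
    """Load a YAML or TOML config file and validate every block."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text())
    return parse_config(data or {})


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML; load_and_validate round-trips it."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
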