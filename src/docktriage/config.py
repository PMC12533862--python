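"""Run configuration: one YAML file carrying every threshold in the pipeline.

The defaults are the screen's published constants — 5 Å close contact,
5.5 Å early stop, 10 Å censor value, the 9–10 ns ranking window, three MD
replicates and a 1% enrichment fraction. Unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .interactions import HBondCriteria
from .stability import StabilityConfig
from .triage import TriageThresholds

__all__ = ["RunConfig", "ScreenSection", "InteractionSection", "StabilitySection"]


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class ScreenSection:
    table: str | None = None
    fraction: float = 0.01
    lower_is_better: bool = True
    score_threshold: float | None = None
    overlap_threshold: float | None = None
    require_clinical_inclusion: bool = False

    def thresholds(self) -> TriageThresholds:
        return TriageThresholds(
            score_threshold=self.score_threshold,
            overlap_threshold=self.overlap_threshold,
            require_clinical_inclusion=self.require_clinical_inclusion,
        )


@dataclass
class InteractionSection:
    contact_cutoff: float = 5.0
    w_hbond: float = 2.0
    w_contact: float = 1.0
    max_da_distance: float = 3.5
    max_ha_distance: float = 2.5
    min_dha_angle: float = 120.0
    heavy_atom_fallback: bool = True

    def criteria(self) -> HBondCriteria:
        return HBondCriteria(
            max_da_distance=self.max_da_distance,
            max_ha_distance=self.max_ha_distance,
            min_dha_angle=self.min_dha_angle,
            heavy_atom_fallback=self.heavy_atom_fallback,
        )


@dataclass
class StabilitySection:
    manifest: str | None = None
    unit: str = "nm"
    early_stop_threshold: float = 5.5
    censor_value: float = 10.0
    expected_replicates: int = 3
    window: tuple[float, float] = (9.0, 10.0)
    binding_threshold: float = 5.5
    censor_whole_replicate: bool = False

    def stability_config(self) -> StabilityConfig:
        return StabilityConfig(
            early_stop_threshold=self.early_stop_threshold,
            censor_value=self.censor_value,
            expected_replicates=self.expected_replicates,
            window=tuple(self.window),
            binding_threshold=self.binding_threshold,
            censor_whole_replicate=self.censor_whole_replicate,
        )


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    screen: ScreenSection = field(default_factory=ScreenSection)
    interactions: InteractionSection = field(default_factory=InteractionSection)
    stability: StabilitySection = field(default_factory=StabilitySection)
    output_dir: str = "triage_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        sections = {}
        for name, section_cls in (
            ("screen", ScreenSection),
            ("interactions", InteractionSection),
            ("stability", StabilitySection),
        ):
            if name in data:
                sections[name] = _from_mapping(section_cls, data.pop(name) or {}, name)
        return cls(**sections, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})

    def dump(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)
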