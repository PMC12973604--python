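"""Run configuration: serializable parameters for the whole pipeline.

A :class:`RunConfig` fully determines a run together with the seed: the
synthetic-population settings, the error and event models, the comparator
thresholds, the confidence pattern table, the acceptance strategy, and the
report year. Round-trips through YAML; unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .classify import DEFAULT_PATTERN_TABLE, ConfidencePatternTable
from .matching import DEFAULT_NAME_RULES, NameRules
from .synth import DEFAULT_ERROR_MODEL, DEFAULT_EVENT_MODEL, ErrorModel, EventModel

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    seed: int = 0
    n_persons: int = 5000
    overlap: float = 0.85
    birth_year_range: tuple[int, int] = (1900, 1954)
    years: tuple[int, int] = (2007, 2019)
    report_year: int = 2019
    death_cutoff_year: int = 2007
    strategy: int = 5
    out_dir: str = "out"
    error_model: ErrorModel = field(default_factory=lambda: DEFAULT_ERROR_MODEL)
    event_model: EventModel = field(default_factory=lambda: DEFAULT_EVENT_MODEL)
    name_rules: NameRules = field(default_factory=lambda: DEFAULT_NAME_RULES)
    pattern_table: ConfidencePatternTable = field(default_factory=lambda: DEFAULT_PATTERN_TABLE)

    def __post_init__(self):
        if self.strategy not in range(1, 6):
            raise ConfigError(f"strategy must be 1..5, got {self.strategy}")
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigError("overlap must be in [0, 1]")
        if self.years[1] < self.years[0]:
            raise ConfigError(f"empty year window: {self.years}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_persons": self.n_persons,
            "overlap": self.overlap,
            "birth_year_range": list(self.birth_year_range),
            "years": list(self.years),
            "report_year": self.report_year,
            "death_cutoff_year": self.death_cutoff_year,
            "strategy": self.strategy,
            "out_dir": self.out_dir,
            "error_model": self.error_model.to_dict(),
            "event_model": self.event_model.to_dict(),
            "name_rules": self.name_rules.to_dict(),
            "pattern_table": self.pattern_table.to_list(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        try:
            if "birth_year_range" in kwargs:
                kwargs["birth_year_range"] = tuple(kwargs["birth_year_range"])
            if "years" in kwargs:
                kwargs["years"] = tuple(kwargs["years"])
            if "error_model" in kwargs:
                kwargs["error_model"] = ErrorModel.from_dict(kwargs["error_model"])
            if "event_model" in kwargs:
                kwargs["event_model"] = EventModel.from_dict(kwargs["event_model"])
            if "name_rules" in kwargs:
                kwargs["name_rules"] = NameRules.from_dict(kwargs["name_rules"])
            if "pattern_table" in kwargs:
                kwargs["pattern_table"] = ConfidencePatternTable.from_list(kwargs["pattern_table"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(raw)
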