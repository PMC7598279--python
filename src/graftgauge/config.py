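"""Run configuration: one object tying together cohort, rheology, waveforms.

Serialisable to YAML (JSON is valid YAML, so JSON configs load too). A run
uses either a synthetic cohort spec (with a seed) or a manifest of existing
STL files — exactly one of the two.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .hemodynamics import RheologyParams
from .synthetic_anatomy import AnatomyParams, CohortSpec

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    cohort: CohortSpec | None = field(default_factory=CohortSpec)
    manifest: str | None = None
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    rheology: RheologyParams = field(default_factory=RheologyParams)
    waveform_kinds: tuple[str, ...] = ("flat", "sharp", "real")
    peak_velocity: float = 0.5  # m/s
    period: float = 1.0  # s
    n_time_steps: int = 64
    n_stations: int = 40
    output_dir: str = "graftgauge_out"
    verbosity: str = "info"

    def validate(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ConfigError("exactly one of cohort spec or manifest is required")
        if self.cohort is not None:
            self.cohort.validate()
        self.anatomy.validate()
        self.rheology.validate()
        if not self.waveform_kinds:
            raise ConfigError("at least one waveform kind is required")
        if self.verbosity not in ("quiet", "info", "debug"):
            raise ConfigError("verbosity must be quiet, info or debug")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["waveform_kinds"] = list(self.waveform_kinds)
        return out

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if data.get("cohort") is not None:
            data["cohort"] = CohortSpec(**data["cohort"])
        if data.get("anatomy") is not None:
            data["anatomy"] = AnatomyParams(**data["anatomy"])
        if data.get("rheology") is not None:
            data["rheology"] = RheologyParams(**data["rheology"])
        if "waveform_kinds" in data:
            data["waveform_kinds"] = tuple(data["waveform_kinds"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
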