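"""Run configuration: one YAML-serializable bundle of every tunable.

``RunConfig`` groups the parameter dataclasses of the individual stages so
a whole analysis (or simulation) is reproducible from one file.  Loading
rejects unknown keys, so typos fail loudly instead of silently falling
back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiments import PipelineConfig
from .simulate import HeartModelParams, RadarParams, RespModelParams, ScenarioParams

__all__ = ["RunConfig"]


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section '{context}'; "
            f"valid keys: {sorted(known)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the simulate → demod → enhance → beats chain."""

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    heart: HeartModelParams = field(default_factory=HeartModelParams)
    resp: RespModelParams = field(default_factory=RespModelParams)
    radar: RadarParams = field(default_factory=RadarParams)

    _SECTIONS = {
        "pipeline": PipelineConfig,
        "scenario": ScenarioParams,
        "heart": HeartModelParams,
        "resp": RespModelParams,
        "radar": RadarParams,
    }

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name)) for name in self._SECTIONS}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("configuration root must be a mapping")
        unknown = set(data) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(
                f"unknown section(s) {sorted(unknown)}; valid sections: "
                f"{sorted(cls._SECTIONS)}"
            )
        kwargs = {
            name: _from_mapping(section_cls, data.get(name, {}) or {}, name)
            for name, section_cls in cls._SECTIONS.items()
        }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
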