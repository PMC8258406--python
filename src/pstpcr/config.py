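"""Serializable run configuration shared by the CLI subcommands."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .amplify import AmplifyConfig, ThermalProfile
from .primer_design import DesignRules
from .thermo import ThermoConditions


@dataclass
class RunConfig:
    """Everything a run needs; defaults reproduce the published protocol."""

    profile: ThermalProfile = field(default_factory=ThermalProfile)
    amplify: AmplifyConfig = field(default_factory=AmplifyConfig)
    rules: DesignRules = field(default_factory=DesignRules)
    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    seed: int = 0
    outdir: str = "pstpcr_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for name, sub_cls in (
            ("profile", ThermalProfile),
            ("amplify", AmplifyConfig),
            ("rules", DesignRules),
            ("conditions", ThermoConditions),
        ):
            if name in data:
                sub = dict(data[name])
                for key, value in sub.items():
                    if isinstance(value, list):
                        sub[key] = tuple(value)
                if name == "amplify" and "conditions" in sub:
                    sub["conditions"] = ThermoConditions(**sub["conditions"])
                kwargs[name] = sub_cls(**sub)
        for name in ("seed", "outdir"):
            if name in data:
                kwargs[name] = data[name]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
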