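"""Declarative pipeline configuration.

One document holds every tunable the stages consume; unknown keys are
rejected and a round-trip through YAML reproduces the object exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import SimConfig


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    n_perm: int = 1000
    min_reads: int = 10
    pad: int = 75
    dicermin: int = 20
    dicermax: int = 24
    foldsize: int = 300
    promoter_length: int = 2000
    identity_threshold: float = 0.8
    expectation_cutoff: float = 5.0
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        sim_doc = doc.pop("sim", {})
        sim_fields = {f.name for f in fields(SimConfig)}
        unknown = set(sim_doc) - sim_fields
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        own_fields = {f.name for f in fields(cls)} - {"sim"}
        unknown = set(doc) - own_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mature_length_weights" in sim_doc:
            sim_doc["mature_length_weights"] = {
                int(k): float(v) for k, v in sim_doc["mature_length_weights"].items()
            }
        for key in ("mite_length_range", "hosting_mite_length_range"):
            if key in sim_doc:
                sim_doc[key] = tuple(sim_doc[key])
        return cls(sim=SimConfig(**sim_doc), **doc)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["sim"]["mite_length_range"] = list(doc["sim"]["mite_length_range"])
        doc["sim"]["hosting_mite_length_range"] = list(doc["sim"]["hosting_mite_length_range"])
        return doc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
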