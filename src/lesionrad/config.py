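"""Run configuration binding the pipeline stages together.

A :class:`RunConfig` is fully JSON-serialisable; re-running a persisted
config reproduces identical outputs because every source of randomness is
fanned out from the single root ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from lesionrad.features.extract import ExtractionConfig
from lesionrad.synthetic import SynthConfig


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    modality_cap: int = 10
    fusion_cap: int = 8
    sfs_trees: int = 50
    cv: int = 5
    patience: int | None = 3


@dataclass
class ModelConfig:
    n_trees: int = 500
    cv_folds: int = 10
    n_bootstrap: int = 1000


@dataclass
class RunConfig:
    seed: int = 0
    positive_class: str = "NMO"
    n_train: int = 86
    synth: SynthConfig = field(default_factory=SynthConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        # the root seed drives every stage deterministically
        self.synth.seed = self.seed

    def stage_seed(self, stage: str) -> int:
        offsets = {"simulate": 0, "split": 1, "select": 2, "train": 3,
                   "evaluate": 4, "explain": 5}
        return (self.seed * 7919 + offsets[stage]) % (2**31)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = self.synth.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d:
            d["synth"] = SynthConfig.from_dict(d["synth"])
        if "extraction" in d:
            e = dict(d["extraction"])
            if "log_sigmas" in e:
                e["log_sigmas"] = tuple(e["log_sigmas"])
            d["extraction"] = ExtractionConfig(**e)
        if "selection" in d:
            d["selection"] = SelectionConfig(**d["selection"])
        if "model" in d:
            d["model"] = ModelConfig(**d["model"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
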