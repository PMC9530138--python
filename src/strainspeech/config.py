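"""Run configuration: one document driving the whole pipeline.

A :class:`RunConfig` nests the simulator, preprocessing, model and
evaluation settings plus one global seed from which every stage seed is
derived (sim = seed, model init/shuffle = seed + 1, evaluation splits =
seed + 2), so a run is reproducible from the config alone. Configs
round-trip losslessly through dicts and YAML/JSON files, and every artifact
a run writes carries the SHA-256 hash of the canonical config document.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .preprocess import PreprocessConfig
from .simulate import SimConfig

__all__ = ["ModelConfig", "EvalConfig", "RunConfig", "config_hash"]


@dataclass(frozen=True)
class ModelConfig:
    conv_channels: tuple = (8, 16, 16, 32, 32, 64, 64)
    fc_sizes: tuple = (256, 128)
    axis_order: str = "hwt"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 50

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        d["fc_sizes"] = list(self.fc_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("conv_channels", "fc_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class EvalConfig:
    k: int = 5
    run_baselines: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalConfig":
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    dataset_path: Optional[str] = None  # load instead of simulate when set
    simulate: bool = True

    def __post_init__(self) -> None:
        if not self.simulate and self.dataset_path is None:
            raise ValueError("either enable simulation or provide dataset_path")

    # stage seeds, all derived from the single global seed
    @property
    def sim_seed(self) -> int:
        return int(self.seed)

    @property
    def model_seed(self) -> int:
        return int(self.seed) + 1

    @property
    def eval_seed(self) -> int:
        return int(self.seed) + 2

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sim": self.sim.to_dict(),
            "preprocess": self.preprocess.to_dict(),
            "model": self.model.to_dict(),
            "eval": self.eval.to_dict(),
            "dataset_path": self.dataset_path,
            "simulate": self.simulate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seed = int(d.get("seed", 0))
        sim = dict(d.get("sim", {}))
        sim.setdefault("seed", seed)  # stage seed derives from the global one
        return cls(
            seed=seed,
            sim=SimConfig.from_dict(sim),
            preprocess=PreprocessConfig.from_dict(d.get("preprocess", {})),
            model=ModelConfig.from_dict(d.get("model", {})),
            eval=EvalConfig.from_dict(d.get("eval", {})),
            dataset_path=d.get("dataset_path"),
            simulate=bool(d.get("simulate", True)),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form of the config."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
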