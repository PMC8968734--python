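"""Run configuration: every pipeline default in one serializable object."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chanvese import CVParams
from .csvm import KernelParams
from .glcm import TextureConfig
from .phantom import PhantomSpec
from .registration import RegParams


@dataclass(frozen=True)
class RunConfig:
    """The resolved settings of one toolkit run.

    Round-trips losslessly through YAML; reports echo it so results are
    self-describing.
    """

    seed: int = 0
    n_train: int = 1500
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cv: CVParams = field(default_factory=CVParams)
    texture: TextureConfig = field(default_factory=TextureConfig)
    kernel: KernelParams = field(default_factory=KernelParams)
    registration: RegParams = field(default_factory=RegParams)

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed,
            phantom=dataclasses.replace(self.phantom, seed=seed),
            registration=dataclasses.replace(self.registration, seed=seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["tissue_means"] = dict(d["phantom"]["tissue_means"])
        d["texture"]["thetas"] = list(d["texture"]["thetas"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        parts = {
            "phantom": PhantomSpec, "cv": CVParams, "texture": TextureConfig,
            "kernel": KernelParams, "registration": RegParams,
        }
        kwargs = {}
        for key, typ in parts.items():
            if key in d:
                sub = dict(d.pop(key))
                if key == "texture" and "thetas" in sub:
                    sub["thetas"] = tuple(sub["thetas"])
                kwargs[key] = typ(**sub)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Short stable hash of the resolved configuration, for logging."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
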