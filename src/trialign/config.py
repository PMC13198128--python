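"""Run configuration schema: nested, validated, digest-stamped.

A run is fully reconstructible from the config copy emitted next to its
outputs; every random behaviour has an explicit seed field and unknown
keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .alignment import AlignmentConfig
from .encoders import EncoderConfig, desk_configs, full_configs
from .synthetic_data import SyntheticSpec


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Section):
    index_path: Optional[str] = None
    max_len: int = 300


class EncodersSection(_Section):
    scale: str = "desk"  # "desk" | "full"
    shared_dim: Optional[int] = None
    seed: int = 0

    def build(self) -> dict:
        if self.scale == "desk":
            return desk_configs(shared_dim=self.shared_dim or 64, seed=self.seed)
        if self.scale == "full":
            return full_configs(shared_dim=self.shared_dim or 512, seed=self.seed)
        raise ValueError(f"unknown scale {self.scale!r}")


class AlignmentSection(_Section):
    temperature: float = 0.07
    w_seq_struct: float = 1.0
    w_seq_text: float = 1.0
    sta_weight: float = 0.0
    batch_struct: int = 80
    batch_text: int = 80
    lr: float = 5e-6
    weight_decay: float = 1e-4
    epochs: int = 20
    total_steps: Optional[int] = None
    warmup: int = 0
    loss_reduction: str = "sum"
    bidirectional: bool = False
    with_replacement: bool = False
    seed: int = 0

    def build(self) -> AlignmentConfig:
        return AlignmentConfig(**self.model_dump())


class SyntheticSection(_Section):
    n: int = 600
    K: int = 8
    motif_len: int = 5
    id_code_len: int = 4
    structure_coverage: float = 0.5
    noise_sigma: float = 0.1
    background_length: tuple = (25, 40)
    seed: int = 0

    def build(self) -> SyntheticSpec:
        d = self.model_dump()
        d["background_length"] = tuple(d["background_length"])
        return SyntheticSpec(**d)


class TaskSection(_Section):
    task: str = "binary_peptide"
    seeds: tuple = (0, 1, 2, 3, 4)
    split_frac: float = 0.8
    seed: int = 0


class OutputSection(_Section):
    out_dir: str = "runs/out"
    overwrite: bool = False


class RunConfig(_Section):
    data: DataSection = DataSection()
    encoders: EncodersSection = EncodersSection()
    alignment: AlignmentSection = AlignmentSection()
    synthetic: SyntheticSection = SyntheticSection()
    task: TaskSection = TaskSection()
    output: OutputSection = OutputSection()

    def digest(self) -> str:
        doc = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        doc = self.model_dump()
        doc["config_digest"] = self.digest()
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(doc, default=str)), sort_keys=True))
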