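"""Configuration dataclasses and YAML (de)serialization.

Defaults are CPU desk-scale: the architecture widths are deliberately small
so a five-fold cross-validation run on a synthetic cohort finishes in
minutes on one core. Every value can be raised through YAML or keyword
overrides for larger experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["EncoderConfig", "BridgeConfig", "TrainConfig", "RunConfig",
           "load_config", "config_hash"]


@dataclass
class EncoderConfig:
    patch_dim: int = 1024          # input patch embedding dimension
    d_wsi: int = 128               # slide embedding width
    n_heads: int = 4
    n_layers: int = 2
    n_landmarks: int = 16          # Nystrom landmarks
    exact_attention_ratio: int = 4  # exact softmax when tokens <= ratio*landmarks
    ppeg_kernels: tuple[int, ...] = (7, 5, 3)
    use_ppeg: bool = True
    wsi_pooling: str = "transformer"  # or "gated_attention"
    d_omics: int = 64              # omics embedding width
    snn_hidden: int = 64
    snn_dropout: float = 0.3


@dataclass
class BridgeConfig:
    mode: str = "bridge"           # bridge | single_directional | non_bridge
    lam: float = 0.5               # weight of the bridge alignment loss
    hidden: int = 128              # bridge MLP hidden width


@dataclass
class TrainConfig:
    n_bins: int = 4                # discrete-time hazard bins
    head_hidden: int = 64
    epochs: int = 8
    lr: float = 1e-3
    weight_decay: float = 1e-4
    accum_steps: int = 4           # gradient accumulation over slides
    # probability of routing the pseudo-omics embedding (bridge output)
    # through the fusion head during multimodal training; trains the head
    # to consume bridge-generated embeddings, which both regularizes the
    # fusion and strengthens missing-modality inference
    modality_dropout: float = 0.5
    seed: int = 0


@dataclass
class RunConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    bridge: BridgeConfig = field(default_factory=BridgeConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_folds: int = 5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for section in ("encoder", "bridge", "train"):
            for k, v in d.get(section, {}).items():
                sub = getattr(cfg, section)
                if not hasattr(sub, k):
                    raise ValueError(f"unknown config key {section}.{k}")
                if k == "ppeg_kernels":
                    v = tuple(v)
                setattr(sub, k, v)
        if "n_folds" in d:
            cfg.n_folds = int(d["n_folds"])
        return cfg


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
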