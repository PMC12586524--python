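"""Experiment configuration (YAML-backed, dataclass defaults).

Every default below is the package's study condition: federated rounds
T=60, 10 local epochs of Adam at lr 5e-4 with batch size 16, and DP
budget epsilon=10 on the spectral summaries.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["ExperimentConfig", "LabelsConfig", "AutoencoderConfig", "SpectralConfig",
           "BackboneConfig", "FederationConfig", "AblationConfig"]


@dataclass
class LabelsConfig:
    embedding_provider: str = "hash"
    embedding_dim: int = 64
    smoothing_eps: float = 1.0
    similarity_threshold: object = "mean"  # float or "mean"
    weight_mode: str = "ratio"  # or "softmax"


@dataclass
class AutoencoderConfig:
    heads: int = 4
    hidden_dim: int = 32
    mask_rate: float = 0.15
    epochs: int = 100
    lr: float = 1e-3
    seed: int = 0


@dataclass
class SpectralConfig:
    M: int = 8
    N_max: int = 32
    epsilon: float = 10.0
    delta_f: object = "auto"  # "auto" (replace-one bound) or float
    seed: int = 0


@dataclass
class BackboneConfig:
    hidden: tuple = (64, 64)
    heads: tuple = (4, 4, 1)
    leaky_slope: float = 0.2
    head_hidden: int = 64


@dataclass
class FederationConfig:
    rounds: int = 60
    local_epochs: int = 10
    lr: float = 5e-4
    batch_size: int = 16
    mode: str = "sync"  # or "async"
    n_groups: object = "auto"  # int or "auto" (eigengap)
    weighted_group_average: bool = False  # sample-size weighted within-group mean
    gating: str = "trace"  # or "offdiag_mean"
    test_fraction: float = 0.2
    loss_mode: str = "two_stage"  # or "joint"


@dataclass
class AblationConfig:
    weighted: bool = False  # drop the label-frequency weighting
    graph: bool = False  # drop the label-graph encoding F
    multiscale: bool = False  # single-scale autoencoder
    asyagg: bool = False  # plain sample-weighted FedAvg instead of clustered fusion


@dataclass
class ExperimentConfig:
    labels: LabelsConfig = field(default_factory=LabelsConfig)
    ae: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    federation: FederationConfig = field(default_factory=FederationConfig)
    ablate: AblationConfig = field(default_factory=AblationConfig)

    @property
    def ae_scales(self) -> tuple:
        return (1,) if self.ablate.multiscale else (1, 2, 3)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cfg = cls()
        for section, values in (d or {}).items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            for key, val in (values or {}).items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                if isinstance(getattr(sub, key), tuple) and isinstance(val, list):
                    val = tuple(val)
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)
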