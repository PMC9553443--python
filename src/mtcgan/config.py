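"""Model and run configuration.

:class:`ModelConfig` is the in-library configuration (a plain dataclass);
:class:`RunConfig` is the schema-validated CLI-facing configuration read from
YAML/JSON, which rejects unknown keys.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .encoders import MtfeConfig

__all__ = ["ModelConfig", "RunConfig", "desk_profile", "compact_profile", "load_run_config"]

GRANULARITIES = ("char", "sentence", "paragraph", "chapter")


@dataclass
class ModelConfig:
    # multigranularity encoders
    d_model: int = 128
    gru_hidden: int = 64
    article_dim: int = 64
    n_layers: int = 6
    n_heads: int = 8
    dropout: float = 0.3
    encoder_block: str = "paper"
    positional_encoding: str = "none"
    share_embeddings: bool = False
    granularities: tuple[str, ...] = GRANULARITIES
    # entity-distribution seed
    seed_d_emb: int = 16
    seed_mode: str = "distribution"  # | "random"
    seed_rng: int = 12345
    # conditionally enhanced U-Net
    seed_len: int = 64
    seed_channels: int = 4
    lsfe_channels: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    decoder_channels: tuple[int, ...] = (64, 32, 32, 16, 16, 16)
    d_condition: int = 64
    d_head: int = 64
    # discriminator
    disc_channels: int = 32
    disc_layers: int = 7
    # optimisation
    lr: float = 1e-4
    lr_decay: float = 0.95
    epochs: int = 20
    k_disc: int = 1
    batch_size: int = 16
    lambda_adv: float = 1.0
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    clip_norm: float = 5.0
    # data / decoding
    min_count: int = 1
    crf_hard_mask: bool = True
    crf_iters: int = 80
    eval_dev_every: int = 1  # per-epoch dev evaluation cadence; 0 = final only
    # ablation switches
    main_input: str = "attention"  # | "noise"
    condition: str = "Y"  # | "L"
    freeze_discriminator: bool = False  # pure supervised mode (with lambda_adv=0)

    def __post_init__(self):
        if self.seed_len % 64 != 0:
            raise ValueError("seed_len must be a multiple of 64 (6 halvings)")
        if len(self.lsfe_channels) != 6 or len(self.decoder_channels) != 6:
            raise ValueError("U-Net encoder/decoder must both have 6 levels")
        if self.k_disc < 1:
            raise ValueError("k_disc must be >= 1")
        if self.main_input not in ("attention", "noise"):
            raise ValueError(f"unknown main_input {self.main_input!r}")
        if self.condition not in ("Y", "L"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.seed_mode not in ("distribution", "random"):
            raise ValueError(f"unknown seed_mode {self.seed_mode!r}")
        self.granularities = tuple(self.granularities)
        self.mtfe()  # validates encoder settings

    def mtfe(self) -> MtfeConfig:
        return MtfeConfig(
            d_model=self.d_model,
            gru_hidden=self.gru_hidden,
            article_dim=self.article_dim,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            dropout=self.dropout,
            encoder_block=self.encoder_block,
            positional_encoding=self.positional_encoding,
            granularities=self.granularities,
        )

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def desk_profile(**overrides) -> ModelConfig:
    """Compact configuration for CPU-scale corpora (hundreds of sentences).

    Smaller widths than the defaults and a learning rate matched to the small
    number of optimisation steps such corpora provide per epoch.
    """
    cfg = ModelConfig(
        d_model=64,
        gru_hidden=32,
        article_dim=32,
        seed_d_emb=8,
        lsfe_channels=(8, 8, 16, 16, 32, 32),
        decoder_channels=(32, 16, 16, 8, 8, 8),
        d_condition=48,
        d_head=64,
        disc_channels=16,
        dropout=0.1,
        lr=3e-3,
        crf_iters=40,
    )
    return replace(cfg, **overrides) if overrides else cfg


def compact_profile(**overrides) -> ModelConfig:
    """Minimal configuration for ablation sweeps on very small corpora."""
    cfg = desk_profile(
        d_model=32,
        gru_hidden=24,
        article_dim=16,
        d_condition=32,
        d_head=48,
        disc_channels=12,
        lsfe_channels=(8, 8, 8, 8, 16, 16),
        decoder_channels=(16, 8, 8, 8, 8, 8),
        epochs=10,
    )
    return replace(cfg, **overrides) if overrides else cfg


class RunConfig(BaseModel):
    """CLI run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    profile: Literal["default", "desk", "compact"] = "desk"
    model: dict = Field(default_factory=dict)  # ModelConfig overrides
    rng_seed: int = 0
    train_path: str | None = None
    dev_path: str | None = None
    doc_type: Literal["canon", "medical_cases", "herbal", "comprehensive"] = "comprehensive"
    catalog_path: str | None = None
    # synthetic-data fallback when no train_path is given
    synth_regime: Literal["easy", "hard"] = "easy"
    synth_train_sentences: int = 500
    synth_dev_sentences: int = 100

    def model_cfg(self) -> ModelConfig:
        base = {
            "default": ModelConfig,
            "desk": desk_profile,
            "compact": compact_profile,
        }[self.profile]()
        if self.model:
            valid = set(ModelConfig.__dataclass_fields__)
            unknown = set(self.model) - valid
            if unknown:
                raise ValueError(f"unknown model config keys: {sorted(unknown)}")
            fixed = {
                k: tuple(v) if isinstance(v, list) else v for k, v in self.model.items()
            }
            base = replace(base, **fixed)
        return base


def load_run_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    return RunConfig(**payload)
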