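"""Run configuration: every tunable of every stage, schema-checked.

A single :class:`RunConfig` drives a whole run (simulate -> similarities ->
embeddings -> graphs -> model -> evaluation). Unknown keys are rejected so a
typo in a YAML file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from lncgraph.types import DISEASE_VIEWS, LNCRNA_VIEWS

ABLATION_VARIANTS = (
    "full",        # GCN-GAT-GCN on both graphs + attention fusion
    "gcn",         # GCN-GCN stack, no attention layer
    "gat",         # GAT-GAT stack, no convolution layers
    "noatt",       # both views, fusion replaced by element-wise mean
    "rfg",         # feature graph only
    "cg",          # interconnected graph only
    "rwr",         # raw RWR features, no autoencoder compression
)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimilarityConfig(_Section):
    bandwidth_mode: str = "profile-normalized"  # or "fixed"
    sigma: float = Field(default=1.0, gt=0)     # used when bandwidth_mode == "fixed"
    disease_gip: bool = False                   # disease-side GIP view (off by default)
    minmax_semantic: bool = True
    views: dict[str, bool] = Field(
        default_factory=lambda: {v: True for v in LNCRNA_VIEWS + DISEASE_VIEWS}
    )

    @model_validator(mode="after")
    def _check(self) -> "SimilarityConfig":
        if self.bandwidth_mode not in ("fixed", "profile-normalized"):
            raise ValueError("bandwidth_mode must be 'fixed' or 'profile-normalized'")
        unknown = set(self.views) - set(LNCRNA_VIEWS + DISEASE_VIEWS)
        if unknown:
            raise ValueError(f"unknown omic views in config: {sorted(unknown)}")
        return self


class RwrConfig(_Section):
    c: float = Field(default=0.5, gt=0, lt=1)  # weight on the walk term
    tolerance: float = Field(default=1e-6, gt=0)
    max_iterations: int = Field(default=1000, ge=1)


class DaeConfig(_Section):
    hidden_dim: int = Field(default=4, ge=1)
    corruption: float = Field(default=0.1, ge=0, lt=1)
    epochs: int = Field(default=500, ge=1)
    learning_rate: float = Field(default=1e-3, gt=0)


class PairGraphConfig(_Section):
    k_neighbors: int = Field(default=5, ge=1)


class ModelConfig(_Section):
    gcn1_dim: int = Field(default=32, ge=1)
    gat_dim: int = Field(default=16, ge=1)
    gcn3_dim: int = Field(default=16, ge=1)
    attention_dim: int = Field(default=16, ge=1)  # d_l of the fusion layer
    mlp_hidden: list[int] = Field(default_factory=lambda: [32, 16])
    dropout: float = Field(default=0.1, ge=0, lt=1)


class TrainConfig(_Section):
    epochs: int = Field(default=200, ge=1)
    learning_rate: float = Field(default=5e-3, gt=0)
    patience: int = Field(default=25, ge=1)
    val_fraction: float = Field(default=0.2, gt=0, lt=0.5)


class EvalConfig(_Section):
    k_folds: int = Field(default=5)
    negative_ratio: float = Field(default=1.0, gt=0)
    threshold: float = Field(default=0.5, gt=0, lt=1)
    per_fold_negatives: bool = False  # default: one global negative sample, then folded
    fold_safe_gip: bool = True        # recompute GIP per fold with test cells zeroed

    @model_validator(mode="after")
    def _check(self) -> "EvalConfig":
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        return self


class RunConfig(_Section):
    seed: int = 0
    variant: str = "full"
    similarity: SimilarityConfig = Field(default_factory=SimilarityConfig)
    rwr: RwrConfig = Field(default_factory=RwrConfig)
    dae: DaeConfig = Field(default_factory=DaeConfig)
    pair_graph: PairGraphConfig = Field(default_factory=PairGraphConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.variant not in ABLATION_VARIANTS:
            raise ValueError(
                f"variant {self.variant!r} not in {ABLATION_VARIANTS}"
            )
        return self

    def config_hash(self) -> str:
        """Stable hash of the full configuration (order-independent)."""
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; unknown keys are an error."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)
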