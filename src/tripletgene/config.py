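"""Run configuration: YAML schema, strict validation, overrides.

A run config binds a data source (synthetic generator or file paths), the
embedding architecture, the training hyperparameters, the loss terms and the
evaluation settings into one reproducible experiment description. Unknown
keys are rejected rather than silently ignored; hyperparameters are
restricted to the published grids unless ``strict_grids: false`` is set.
"""

from __future__ import annotations

import platform
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import yaml

from .losses import ALPHA_GRID, LossConfig
from .model import EMBEDDING_DIM_GRID, EmbeddingModelSpec
from .synthetic import SyntheticConfig
from .training import LEARNING_RATE_GRID, TrainingConfig

__all__ = ["RunConfig", "load_run_config"]

_SECTION_KEYS: dict[str, set[str]] = {
    "data": {"expression", "labels", "clinical", "delimiter", "synthetic"},
    "synthetic": {
        "n_samples", "n_genes", "n_informative", "effect_size",
        "class_balance", "clinical", "seed",
    },
    "model": {
        "kernel_size", "n_filters", "pool_size", "embedding_dim",
        "init_seed", "normalize_embedding",
    },
    "training": {
        "learning_rate", "batch_size", "n_triplets", "val_n_triplets",
        "patience", "min_semi_hard", "max_epochs", "hard_supplement_k",
        "strict_mining", "mine_per_batch", "seed",
    },
    "loss": {"margin", "alpha", "metric",
             "use_triplet", "use_switching", "use_angular"},
    "evaluation": {"k_folds", "val_fraction", "classifier_lr", "classifier_epochs"},
}
_TOP_KEYS = {"data", "model", "training", "loss", "evaluation",
             "seed", "outdir", "strict_grids"}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) in {section!r}: {sorted(unknown)}"
        )


@dataclass
class RunConfig:
    """Validated, resolved experiment configuration."""

    data: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    training: dict[str, Any] = field(default_factory=dict)
    loss: dict[str, Any] = field(default_factory=dict)
    evaluation: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "runs"
    strict_grids: bool = True

    def __post_init__(self) -> None:
        _check_keys("data", self.data, _SECTION_KEYS["data"])
        if "synthetic" in self.data:
            _check_keys("data.synthetic", self.data["synthetic"],
                        _SECTION_KEYS["synthetic"])
        _check_keys("model", self.model, _SECTION_KEYS["model"])
        _check_keys("training", self.training, _SECTION_KEYS["training"])
        _check_keys("loss", self.loss, _SECTION_KEYS["loss"])
        _check_keys("evaluation", self.evaluation, _SECTION_KEYS["evaluation"])
        if self.strict_grids:
            self._check_grids()

    def _check_grids(self) -> None:
        lr = self.training.get("learning_rate")
        if lr is not None and lr not in LEARNING_RATE_GRID:
            raise ValueError(
                f"learning_rate {lr} not in grid {LEARNING_RATE_GRID}; "
                "set strict_grids: false to override"
            )
        alpha = self.loss.get("alpha")
        if alpha is not None and float(alpha) not in ALPHA_GRID:
            raise ValueError(
                f"alpha {alpha} not in grid {ALPHA_GRID}; "
                "set strict_grids: false to override"
            )
        dim = self.model.get("embedding_dim")
        if dim is not None and dim not in EMBEDDING_DIM_GRID:
            raise ValueError(
                f"embedding_dim {dim} not in grid {EMBEDDING_DIM_GRID}; "
                "set strict_grids: false to override"
            )

    # -- builders ----------------------------------------------------------
    def synthetic_config(self) -> SyntheticConfig:
        params = dict(self.data.get("synthetic", {}))
        params.setdefault("seed", self.seed)
        return SyntheticConfig(**params)

    def loss_config(self) -> LossConfig:
        return LossConfig(**self.loss)

    def training_config(self) -> TrainingConfig:
        params = dict(self.training)
        params.setdefault("seed", self.seed)
        return TrainingConfig(loss=self.loss_config(), **params)

    def model_spec(self, n_genes: int, n_clinical: int) -> EmbeddingModelSpec:
        params = dict(self.model)
        params.setdefault("init_seed", self.seed)
        return EmbeddingModelSpec(n_genes=n_genes, n_clinical=n_clinical, **params)

    def resolved(self) -> dict[str, Any]:
        """Full config snapshot plus versions, for writing next to outputs."""
        out = asdict(self)
        out["versions"] = {
            "tripletgene": _version(),
            "numpy": np.__version__,
            "python": platform.python_version(),
        }
        return out

    def write_resolved(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)


def _version() -> str:
    from . import __version__

    return __version__


def _set_dotted(cfg: dict, key: str, value: str) -> None:
    parts = key.split(".")
    node = cfg
    for p in parts[:-1]:
        node = node.setdefault(p, {})
        if not isinstance(node, dict):
            raise ValueError(f"cannot override through non-mapping key {p!r}")
    node[parts[-1]] = yaml.safe_load(value)


def load_run_config(
    path=None,
    overrides: dict[str, str] | None = None,
    seed: int | None = None,
    outdir: str | None = None,
) -> RunConfig:
    """Load a YAML run config, apply dotted-key overrides, validate strictly."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("run config must be a YAML mapping")
            raw = loaded
    for key, value in (overrides or {}).items():
        _set_dotted(raw, key, value)
    if seed is not None:
        raw["seed"] = seed
    if outdir is not None:
        raw["outdir"] = outdir
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    return RunConfig(**raw)
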