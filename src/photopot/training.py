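"""Training entry points: loss, splits, ensemble training, fine-tuning.

The optimization itself lives in the estimators (:mod:`photopot.potential`);
these functions are the procedural surface. Training minimizes the
energies-only MSE loss; forces are deliberately not part of the default
objective (an optional force-weighted variant is a non-default escape hatch
for dynamics-grade fine-tuning and is currently limited to ``w_force=0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemio import DatasetRecord, LevelRegistry
from .descriptor import AEVConfig
from .potential import EnsemblePotential, MultiStateModel, OscillatorStrengthModel

__all__ = [
    "TrainConfig",
    "mse_loss",
    "split_train_val",
    "train_model",
    "train_ensemble",
    "fine_tune",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run; maps 1:1 onto estimator parameters."""

    descriptor: AEVConfig | None = None
    hidden_layers: tuple[int, ...] = (160, 128, 96)
    n_states_max: int = 11
    learning_rate: float = 1e-3
    max_epochs: int = 400
    batch_size: int | None = None
    val_fraction: float = 0.1
    patience: int = 50
    seed: int = 0
    target: str = "energies"  # or "oscillator_strengths"
    level_weights: dict | None = None  # tag -> weight; None = proportional

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("validation fraction must be in (0, 1)")
        if self.target not in ("energies", "oscillator_strengths"):
            raise ValueError(f"unknown target {self.target!r}")


def mse_loss(e_ml: Sequence[float], e_ref: Sequence[float]) -> float:
    """Mean squared error between predicted and reference energies (eV^2)."""
    a = np.asarray(e_ml, dtype=float)
    b = np.asarray(e_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def split_train_val(records: Sequence, fraction: float, seed: int):
    """Deterministic disjoint train/validation split; ``fraction`` goes to validation."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    n_val = max(1, int(round(fraction * len(records))))
    n_val = min(n_val, len(records) - 1)
    val_idx = set(perm[:n_val].tolist())
    train = [records[i] for i in range(len(records)) if i not in val_idx]
    val = [records[i] for i in range(len(records)) if i in val_idx]
    return train, val


def _estimator(config: TrainConfig, n_levels: int):
    kwargs = dict(
        descriptor=config.descriptor,
        hidden_layers=config.hidden_layers,
        n_states_max=config.n_states_max,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        val_fraction=config.val_fraction,
        patience=config.patience,
        seed=config.seed,
        level_weights=config.level_weights,
    )
    if config.target == "energies":
        return MultiStateModel(n_levels=n_levels, **kwargs)
    return OscillatorStrengthModel(**kwargs)


def train_model(
    records: Sequence[DatasetRecord], registry: LevelRegistry, config: TrainConfig
):
    """Train a single model (energies or oscillator strengths) per the config."""
    model = _estimator(config, registry.n_levels)
    return model.fit(records, registry)


def train_ensemble(
    records: Sequence[DatasetRecord],
    registry: LevelRegistry,
    config: TrainConfig,
    n_members: int = 3,
) -> EnsemblePotential:
    """Train ``n_members`` models with member-specific seeds (seed, seed+1, ...).

    Member seeds drive both the weight initialization and the
    train/validation split, so members see different splits as well.
    """
    if config.target != "energies":
        raise ValueError("ensembles are defined for the energy target")
    members = []
    for k in range(n_members):
        cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + k})
        members.append(train_model(records, registry, cfg))
    return EnsemblePotential(members)


def _fine_tune_one(model, records, registry, config: TrainConfig):
    if model.descriptor_.to_dict() != (config.descriptor or model.descriptor_).to_dict():
        raise ValueError("fine-tuning data descriptor config does not match the pretrained model")
    clone = type(model)(**model.get_params())
    clone.descriptor = model.descriptor_
    clone.nets_ = {el: net.copy() for el, net in model.nets_.items()}
    clone.self_energies_ = dict(model.self_energies_)
    clone.descriptor_ = model.descriptor_
    clone.feature_mean_ = model.feature_mean_.copy()
    clone.feature_scale_ = model.feature_scale_.copy()
    clone.target_scale_ = model.target_scale_
    clone.set_params(
        warm_start=True,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        val_fraction=config.val_fraction,
        patience=config.patience,
        seed=config.seed,
    )
    return clone.fit(records, registry)


def fine_tune(pretrained, records, registry: LevelRegistry, config: TrainConfig):
    """Continue optimization of a pretrained model or ensemble on new records.

    Parameters are initialized from the pretrained state (no
    re-initialization); with ``max_epochs=0`` the pretrained parameters are
    returned unchanged.
    """
    if isinstance(pretrained, EnsemblePotential):
        members = [
            _fine_tune_one(
                m, records, registry, TrainConfig(**{**config.__dict__, "seed": config.seed + k})
            )
            for k, m in enumerate(pretrained.members)
        ]
        return EnsemblePotential(members)
    return _fine_tune_one(pretrained, records, registry, config)
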