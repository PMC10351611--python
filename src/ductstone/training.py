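"""End-to-end weakly-supervised optimization.

Schedule: RMSProp (rho 0.9, eps 1e-8), batch size 3, initial learning rate
1e-4; the learning rate divides by 10 after 5 epochs without validation
improvement, training stops early after 10, and the checkpoint kept is the
epoch with the best validation loss. An "improvement" must beat the running
best by at least ``improvement_tol``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses as L
from .errors import ConfigError, ValidationError
from .io import DatasetManifest, read_image
from .network import ModelConfig, StoneDetector
from .nn import RMSProp
from .phantom import split_dataset

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "TrainingHistory",
    "TrainResult",
    "train",
    "lr_schedule_step",
    "early_stop_check",
    "make_validation_split",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 3
    initial_lr: float = 1e-4
    rho: float = 0.9
    eps: float = 1e-8
    plateau_patience: int = 5
    plateau_factor: float = 10.0
    early_stop_patience: int = 10
    max_epochs: int = 100
    val_fraction: float = 0.1
    improvement_tol: float = 1e-5
    literal_sign: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ConfigError("patiences must be >= 1")
        if self.plateau_factor <= 1:
            raise ConfigError("plateau_factor must be > 1")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train: dict[str, float]
    val_loss: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def val_losses(self) -> list[float]:
        return [r.val_loss for r in self.records]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["epoch", "lr", "loss_fg", "loss_bg", "loss_con", "loss_cls",
                 "loss_total", "val_loss"]
            )
            for r in self.records:
                writer.writerow(
                    [r.epoch, r.lr, r.train["loss_fg"], r.train["loss_bg"],
                     r.train["loss_con"], r.train["loss_cls"],
                     r.train["loss_total"], r.val_loss]
                )


@dataclass
class TrainResult:
    model: StoneDetector
    history: TrainingHistory


def _epochs_since_improvement(val_losses: list[float], tol: float) -> int:
    """Trailing epoch count since the running best last improved."""
    if not val_losses:
        return 0
    best = val_losses[0]
    since = 0
    for v in val_losses[1:]:
        if v < best - tol:
            best = v
            since = 0
        else:
            since += 1
    return since


def lr_schedule_step(val_losses: list[float], initial_lr: float,
                     config: TrainConfig = TrainConfig()) -> float:
    """Replay the reduce-on-plateau schedule over a validation-loss trace.

    Each run of ``plateau_patience`` consecutive non-improving epochs divides
    the learning rate by ``plateau_factor`` (and restarts the count).
    """
    lr = initial_lr
    best = np.inf
    since = 0
    for v in val_losses:
        if v < best - config.improvement_tol:
            best = v
            since = 0
        else:
            since += 1
            if since >= config.plateau_patience:
                lr /= config.plateau_factor
                since = 0
    return lr


def early_stop_check(val_losses: list[float],
                     config: TrainConfig = TrainConfig()) -> bool:
    """True iff the validation loss has not improved for
    ``early_stop_patience`` consecutive epochs."""
    return _epochs_since_improvement(val_losses, config.improvement_tol) >= config.early_stop_patience


def make_validation_split(manifest: DatasetManifest, val_fraction: float,
                          seed: int) -> tuple[DatasetManifest, DatasetManifest]:
    """Stratified carve-out of a validation set from a training manifest."""
    if not (0 < val_fraction < 1):
        raise ValidationError(f"val_fraction must be in (0, 1), got {val_fraction}")
    train, val, _ = split_dataset(manifest, 1.0 - val_fraction, val_fraction, seed=seed)
    return train, val


def _load_images(manifest: DatasetManifest, image_size: int) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack(
        [read_image(r.path, target_size=image_size) for r in manifest.records]
    )
    return images, manifest.labels.astype(float)


def _dataset_loss(model: StoneDetector, images: np.ndarray, labels: np.ndarray,
                  weights: L.LossWeights, batch_size: int, literal_sign: bool) -> float:
    """Mean total loss over a dataset in eval mode (no dropout)."""
    was_training = model.training
    model.eval()
    total = 0.0
    for start in range(0, len(images), batch_size):
        sl = slice(start, start + batch_size)
        out = model.forward(images[sl])
        _, bundle = L.compute_losses(out, labels[sl], weights, literal_sign)
        total += bundle.total * (sl.indices(len(images))[1] - start)
    if was_training:
        model.train()
    return total / len(images)


def train(
    train_manifest: DatasetManifest,
    val_manifest: DatasetManifest | None,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    loss_weights: L.LossWeights = L.LossWeights(),
) -> TrainResult:
    """Optimize a freshly initialized detector on a labelled manifest.

    Deterministic given the config seeds: data order, dropout and parameter
    initialization all derive from them. Returns the model restored to the
    best-validation-loss checkpoint, plus the full epoch history.
    """
    if len(train_manifest) == 0:
        raise ValidationError("empty training manifest")
    if val_manifest is None:
        train_manifest, val_manifest = make_validation_split(
            train_manifest, train_config.val_fraction, train_config.seed
        )
    if len(val_manifest) == 0:
        raise ValidationError("empty validation manifest")
    labels_present = set(train_manifest.labels.tolist())
    if labels_present != {0, 1}:
        warnings.warn(
            f"training set contains a single class {labels_present}; the "
            "attention losses cannot contrast stone against normal images",
            stacklevel=2,
        )

    model = StoneDetector(model_config)
    seq = np.random.SeedSequence(train_config.seed)
    order_seed, drop_seed = seq.spawn(2)
    model.reseed_dropout(int(drop_seed.generate_state(1)[0]))
    order_rng = np.random.default_rng(order_seed)

    size = model_config.image_size
    train_images, train_labels = _load_images(train_manifest, size)
    val_images, val_labels = _load_images(val_manifest, size)

    opt = RMSProp(model.parameters(), lr=train_config.initial_lr,
                  rho=train_config.rho, eps=train_config.eps)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    lr = train_config.initial_lr
    plateau_since = 0

    for epoch in range(1, train_config.max_epochs + 1):
        model.train()
        perm = order_rng.permutation(len(train_images))
        sums = {k: 0.0 for k in ("loss_fg", "loss_bg", "loss_con", "loss_cls", "loss_total")}
        n_batches = 0
        for start in range(0, len(perm), train_config.batch_size):
            idx = perm[start : start + train_config.batch_size]
            out = model.forward(train_images[idx])
            total, bundle = L.compute_losses(
                out, train_labels[idx], loss_weights, train_config.literal_sign
            )
            model.zero_grad()
            total.backward()
            opt.step()
            for k, v in bundle.as_dict().items():
                sums[k] += v
            n_batches += 1
        train_means = {k: v / n_batches for k, v in sums.items()}

        val_loss = _dataset_loss(model, val_images, val_labels, loss_weights,
                                 train_config.batch_size, train_config.literal_sign)
        history.records.append(EpochRecord(epoch, lr, train_means, val_loss))

        if val_loss < best_val - train_config.improvement_tol:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            plateau_since = 0
        else:
            plateau_since += 1
            if plateau_since >= train_config.plateau_patience:
                lr /= train_config.plateau_factor
                opt.lr = lr
                plateau_since = 0
        if early_stop_check(history.val_losses, train_config):
            break

    history.best_epoch = best_epoch if best_epoch else 1
    model.load_state_dict(best_state)
    model.eval()
    return TrainResult(model, history)
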