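"""End-to-end training loop for the multi-branch segmentation network.

Reproduces the training protocol of the reference pipeline: Adam with an
initial learning rate of 3e-4 multiplied by 0.90 after every 300
batches, batch size 15 for training and 50 for validation, per-epoch
reshuffling of the training set, one-time shuffling of the validation
set, early stopping with a patience of 200 epochs, and a dual
checkpointing policy (every third epoch plus every new validation-loss
best).  Fine-tuning mode lowers the learning rate to 1e-5, saves every
fifth epoch and trains for a 20-epoch budget.
"""

from __future__ import annotations

import contextlib
import csv
import dataclasses
import json
import pathlib

import numpy as np

from .losses import LossSpec, compute_loss
from . import nn as nn_module
from .nn import Adam, Tensor


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes NaN/Inf."""


@dataclasses.dataclass
class TrainConfig:
    """Optimization schedule and checkpoint policy."""

    initial_lr: float = 3e-4
    lr_decay_factor: float = 0.90
    lr_decay_every_n_batches: int = 300
    batch_size_train: int = 15
    batch_size_val: int = 50
    early_stop_patience: int = 200
    checkpoint_stride: int = 3
    max_epochs: int = 1000
    seed: int = 0
    fine_tune: bool = False
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        for f in (
            "initial_lr", "lr_decay_factor", "lr_decay_every_n_batches",
            "batch_size_train", "batch_size_val", "early_stop_patience",
            "checkpoint_stride", "max_epochs",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.fine_tune:
            self.initial_lr = 1e-5
            self.checkpoint_stride = 5
            self.max_epochs = 20


@dataclasses.dataclass
class LossHistory:
    """Per-epoch validation-loss trace with checkpoint availability."""

    val_loss: np.ndarray
    checkpoint_saved: np.ndarray
    best_epoch: int
    train_loss: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.val_loss)

    def to_csv(self, path: str | pathlib.Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "train_loss", "val_loss", "checkpoint"])
            for e in range(len(self.val_loss)):
                tl = "" if self.train_loss is None else self.train_loss[e]
                wr.writerow(
                    [e + 1, tl, self.val_loss[e], int(self.checkpoint_saved[e])]
                )

    @classmethod
    def from_csv(cls, path: str | pathlib.Path) -> "LossHistory":
        vals, flags, trains = [], [], []
        with open(path) as fh:
            for row in csv.DictReader(fh):
                vals.append(float(row["val_loss"]))
                flags.append(bool(int(row["checkpoint"])))
                trains.append(
                    float(row["train_loss"]) if row.get("train_loss") else np.nan
                )
        vals = np.asarray(vals)
        return cls(
            val_loss=vals,
            checkpoint_saved=np.asarray(flags, dtype=bool),
            best_epoch=int(np.argmin(vals)),
            train_loss=np.asarray(trains),
        )


def lr_at(batch_index: int, cfg: TrainConfig) -> float:
    """Stepped decay: initial_lr * factor^floor(batch / every)."""
    steps = batch_index // cfg.lr_decay_every_n_batches
    return cfg.initial_lr * cfg.lr_decay_factor**steps


def _stack_records(records):
    """Records -> (per-modality input arrays, target array)."""
    mods = list(records[0].images.keys())
    inputs = {
        m: np.stack([r.images[m] for r in records])[:, None].astype(np.float32)
        for m in mods
    }
    targets = np.stack(
        [r.label for r in records]
    )[:, None].astype(np.float32)
    return inputs, targets


def _forward_loss(model, records, loss_spec, batch_size, train,
                  optimizer=None, cfg=None, batch_counter=None):
    """One pass over records in minibatches; returns mean batch loss."""
    total = 0.0
    n_batches = 0
    for ofs in range(0, len(records), batch_size):
        chunk = records[ofs : ofs + batch_size]
        inputs, targets = _stack_records(chunk)
        with nn_module.no_grad() if not train else contextlib.nullcontext():
            xs = [Tensor(inputs[m]) for m in inputs]
            pred = model(xs)
            loss = compute_loss(pred, targets, loss_spec)
        value = float(loss.data)
        if not np.isfinite(value):
            raise TrainingDivergedError(
                f"non-finite loss ({value}) encountered"
            )
        if train:
            model.zero_grad()
            loss.backward()
            optimizer.lr = lr_at(batch_counter[0], cfg)
            optimizer.step()
            batch_counter[0] += 1
        total += value
        n_batches += 1
    return total / max(n_batches, 1)


def _save_checkpoint(model, directory, epoch, tag=None):
    path = pathlib.Path(directory)
    path.mkdir(parents=True, exist_ok=True)
    f = path / f"epoch_{epoch:04d}.npz"
    np.savez_compressed(f, **model.state_dict())
    manifest = path / f"epoch_{epoch:04d}.json"
    manifest.write_text(json.dumps({"epoch": epoch, "tag": tag or "stride"}))
    return f


def checkpoint_path(directory, epoch: int) -> pathlib.Path:
    return pathlib.Path(directory) / f"epoch_{epoch:04d}.npz"


def load_checkpoint(model, directory, epoch: int) -> None:
    f = checkpoint_path(directory, epoch)
    with np.load(f) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})


def train(model, train_records, val_records, cfg: TrainConfig,
          loss_spec: LossSpec = LossSpec(), augment_fn=None,
          stop_condition=None):
    """Train the model; returns (model, LossHistory).

    ``augment_fn(record, rng) -> record`` is applied to every training
    record each epoch when given.  The training set is reshuffled every
    epoch; the validation set is shuffled once up front.  Checkpoints are
    written to ``cfg.checkpoint_dir`` (when set) every
    ``checkpoint_stride``-th epoch and at every new validation-loss best.
    ``stop_condition(model, epoch)``, when given, is evaluated after each
    epoch and ends training early when it returns true (used e.g. to halt
    once a target training metric is reached).
    """
    if not train_records or not val_records:
        raise ValueError("empty training or validation record set")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.initial_lr)
    batch_counter = [0]

    val_records = list(val_records)
    rng.shuffle(val_records)  # shuffled once at evaluation start

    train_records = list(train_records)
    val_losses, train_losses, flags = [], [], []
    best = np.inf
    best_epoch = -1

    for epoch in range(1, cfg.max_epochs + 1):
        rng.shuffle(train_records)
        batch = train_records
        if augment_fn is not None:
            batch = [augment_fn(r, rng) for r in batch]
        model.train()
        tl = _forward_loss(
            model, batch, loss_spec, cfg.batch_size_train, True,
            optimizer, cfg, batch_counter,
        )
        model.eval()
        vl = _forward_loss(
            model, val_records, loss_spec, cfg.batch_size_val, False
        )
        train_losses.append(tl)
        val_losses.append(vl)

        saved = False
        if epoch % cfg.checkpoint_stride == 0:
            if cfg.checkpoint_dir:
                _save_checkpoint(model, cfg.checkpoint_dir, epoch)
            saved = True
        if vl < best:
            best = vl
            best_epoch = epoch
            if cfg.checkpoint_dir:
                _save_checkpoint(model, cfg.checkpoint_dir, epoch, tag="best")
            saved = True
        flags.append(saved)

        if epoch - best_epoch >= cfg.early_stop_patience:
            break
        if stop_condition is not None and stop_condition(model, epoch):
            break

    history = LossHistory(
        val_loss=np.asarray(val_losses),
        checkpoint_saved=np.asarray(flags, dtype=bool),
        best_epoch=best_epoch - 1,
        train_loss=np.asarray(train_losses),
    )
    if cfg.checkpoint_dir:
        history.to_csv(pathlib.Path(cfg.checkpoint_dir) / "history.csv")
    return model, history


def fine_tune(model, state_dict, new_train_records, new_val_records,
              cfg: TrainConfig | None = None,
              loss_spec: LossSpec = LossSpec(), augment_fn=None):
    """Domain-adaptation mode: small LR, 20-epoch budget, save stride 5."""
    if cfg is None:
        cfg = TrainConfig(fine_tune=True)
    elif not cfg.fine_tune:
        raise ValueError("fine_tune() requires cfg.fine_tune=True")
    model.load_state_dict(state_dict)
    return train(model, new_train_records, new_val_records, cfg, loss_spec,
                 augment_fn)
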