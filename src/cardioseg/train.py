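"""Training and evaluation.

The model is fitted with Adam (default learning rate 1e-4, batch size 8) on
the multiclass Dice loss; per-epoch training loss and train/val mean IoU,
Dice and F1 are logged to a `TrainingHistory` table, and the weights with
the best validation mean IoU are retained.

The public surface is statsmodels-flavored: `CardiacSegmenter` wraps a
network configuration and `fit()` returns a `FitResult` carrying the
history, the selection diagnostics, `evaluate()` and a `summary()` table.
Thin functional wrappers (`train`, `evaluate`, `checkpoint_roundtrip`) cover
script use.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor
from .errors import ConfigError, NumericError, StructuralError
from .losses import LossConfig, multiclass_dice_loss, one_hot
from .metrics import (MetricsRecord, aggregate_batches, confusion_counts,
                      metrics_from_counts)
from .network import NetworkConfig, SegmentationNet, build_model, count_parameters

Pair = tuple[np.ndarray, np.ndarray]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    seed: int = 0
    device: str = "cpu"
    optimizer: str = "adam"
    # optional hooks, all off by default
    early_stop_val_miou: float | None = None
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.device != "cpu":
            raise ConfigError("only cpu execution is supported")


class TrainingHistory:
    """Per-epoch curve log (loss, mean IoU, mean Dice, mean F1)."""

    COLUMNS = ("epoch", "train_loss", "train_miou", "train_mdice",
               "train_mf1", "val_miou", "val_mdice", "val_mf1")

    def __init__(self):
        self.rows: list[dict] = []

    def append(self, **row) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def moving_average(self, column: str, window: int = 5) -> np.ndarray:
        v = self.to_frame()[column].to_numpy(dtype=float)
        if len(v) < window:
            window = len(v)
        return np.convolve(v, np.ones(window) / window, mode="valid")

    def __len__(self):
        return len(self.rows)


def _collate(pairs: list[Pair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack (H,W) grayscale slices into an N x 3 x H x W batch.

    Grayscale is replicated to three channels to match the encoder stem.
    """
    imgs = np.stack([np.asarray(p[0], dtype=np.float32) for p in pairs])
    masks = np.stack([np.asarray(p[1], dtype=np.int64) for p in pairs])
    if imgs.ndim != 3:
        raise StructuralError("expected single-channel (H, W) images")
    x = np.repeat(imgs[:, None], 3, axis=1)
    return x, masks


def _batches(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def evaluate(model: SegmentationNet, test_set: list[Pair],
             batch_size: int = 8, absent_policy: str = "one") -> MetricsRecord:
    """Per-batch metric records aggregated across batches (mean +/- SD).

    Runs in evaluation mode with no graph construction; weights are never
    touched.
    """
    if not test_set:
        raise ConfigError("test_set is empty")
    was_training = model.training
    model.eval()
    records = []
    order = np.arange(len(test_set))
    try:
        with T.no_grad():
            for idx in _batches(len(test_set), batch_size, order):
                x, masks = _collate([test_set[i] for i in idx])
                pred = model.forward(x).data.argmax(axis=1)
                cc = confusion_counts(pred, masks, model.cfg.n_classes)
                records.append(metrics_from_counts(cc, absent_policy))
    finally:
        model.train(was_training)
    return aggregate_batches(records)


def train(model: SegmentationNet, train_set: list[Pair],
          val_set: list[Pair] | None, train_cfg: TrainConfig | None = None,
          loss_cfg: LossConfig | None = None,
          verbose: bool = False) -> tuple[SegmentationNet, TrainingHistory]:
    """Fit the model; returns it with the best-validation-IoU weights loaded.

    Each epoch: seeded shuffle, mini-batch forward, multiclass Dice loss,
    backprop, Adam step.  Train metrics are accumulated from the same
    forward passes; validation metrics come from `evaluate`.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig(n_classes=model.cfg.n_classes)
    if not train_set:
        raise ConfigError("train_set is empty")
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate,
                  weight_decay=train_cfg.weight_decay)
    history = TrainingHistory()
    best_miou, best_state = -1.0, None
    n = len(train_set)
    C = model.cfg.n_classes
    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses, train_records = [], []
        for bi, idx in enumerate(_batches(n, train_cfg.batch_size, order)):
            x, masks = _collate([train_set[i] for i in idx])
            g = one_hot(masks, C)
            logits = model.forward(x)
            p = T.softmax(logits, axis=1)
            loss = multiclass_dice_loss(p, g, loss_cfg)
            if not np.isfinite(loss.data):
                raise NumericError(f"non-finite loss at epoch {epoch}, "
                                   f"batch {bi}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            pred = p.data.argmax(axis=1)
            train_records.append(
                metrics_from_counts(confusion_counts(pred, masks, C)))
        agg = aggregate_batches(train_records)
        row = dict(epoch=epoch, train_loss=float(np.mean(losses)),
                   train_miou=agg["iou"], train_mdice=agg["dice"],
                   train_mf1=agg["f1"], val_miou=np.nan, val_mdice=np.nan,
                   val_mf1=np.nan)
        if val_set:
            vrec = evaluate(model, val_set, train_cfg.batch_size)
            row.update(val_miou=vrec["iou"], val_mdice=vrec["dice"],
                       val_mf1=vrec["f1"])
            if vrec["iou"] > best_miou:
                best_miou = vrec["iou"]
                best_state = {name: p.data.copy()
                              for name, p in model.named_parameters()}
                best_state.update({"buffer:" + name: b.copy() for name, b
                                   in model.named_buffers()})
        history.append(**row)
        if verbose:
            print(f"epoch {epoch}: loss={row['train_loss']:.4f} "
                  f"train_miou={row['train_miou']:.4f} "
                  f"val_miou={row['val_miou']:.4f}", flush=True)
        if (train_cfg.early_stop_val_miou is not None and val_set
                and row["val_miou"] >= train_cfg.early_stop_val_miou):
            break
    if best_state is not None:
        for name, p in model.named_parameters():
            p.data[...] = best_state[name]
        for name, b in model.named_buffers():
            b[...] = best_state["buffer:" + name]
    return model, history


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegmentationNet, path) -> None:
    """Weights + running statistics + config echo, as a compressed archive."""
    arrays = {"param:" + n: p.data for n, p in model.named_parameters()}
    arrays.update({"buffer:" + n: b for n, b in model.named_buffers()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_checkpoint(path, expected_cfg: NetworkConfig | None = None
                    ) -> SegmentationNet:
    """Rebuild a model from a checkpoint; config mismatches are structural."""
    with np.load(str(path)) as npz:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(npz["config_json"]).decode()))
        if expected_cfg is not None and expected_cfg != cfg:
            raise StructuralError("checkpoint configuration does not match "
                                  "the expected network configuration")
        model = SegmentationNet(cfg)
        for name, p in model.named_parameters():
            stored = npz["param:" + name]
            if stored.shape != p.data.shape:
                raise StructuralError(f"parameter {name} shape mismatch: "
                                      f"{stored.shape} vs {p.data.shape}")
            p.data[...] = stored
        for name, b in model.named_buffers():
            b[...] = npz["buffer:" + name]
    model.eval()
    return model


def checkpoint_roundtrip(model: SegmentationNet, path) -> SegmentationNet:
    """Save then reload; the reloaded model reproduces logits bit-wise."""
    save_checkpoint(model, path)
    return load_checkpoint(path)


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted-model results: curves, selection diagnostics, evaluation."""

    model: SegmentationNet
    history: TrainingHistory
    train_cfg: TrainConfig
    loss_cfg: LossConfig
    best_val_miou: float

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.model)

    def evaluate(self, test_set: list[Pair], batch_size: int | None = None
                 ) -> MetricsRecord:
        return evaluate(self.model, test_set,
                        batch_size or self.train_cfg.batch_size)

    def summary(self) -> str:
        df = self.history.to_frame()
        buf = io.StringIO()
        cfg = self.model.cfg
        print("Cardiac segmentation fit", file=buf)
        print("=" * 60, file=buf)
        print(f"encoder:            {cfg.encoder_variant}", file=buf)
        print(f"decoder channels:   {cfg.decoder_channels}", file=buf)
        print(f"decoder attention:  {cfg.decoder_attention}", file=buf)
        print(f"trainable params:   {self.n_parameters:,}", file=buf)
        print(f"optimizer:          {self.train_cfg.optimizer} "
              f"(lr={self.train_cfg.learning_rate}, "
              f"batch={self.train_cfg.batch_size})", file=buf)
        print(f"epochs:             {len(df)}", file=buf)
        last = df.iloc[-1]
        print(f"final train loss:   {last.train_loss:.4f}", file=buf)
        print(f"final train mIoU:   {last.train_miou:.4f}", file=buf)
        if np.isfinite(last.val_miou):
            print(f"final val mIoU:     {last.val_miou:.4f}", file=buf)
            print(f"best val mIoU:      {self.best_val_miou:.4f} "
                  f"(weights retained)", file=buf)
        return buf.getvalue()


class CardiacSegmenter:
    """Model facade: configure once, `fit` to data, get a `FitResult`."""

    def __init__(self, network_cfg: NetworkConfig | None = None,
                 seed: int = 0):
        self.network_cfg = network_cfg or NetworkConfig()
        self.seed = seed
        self.model = build_model(self.network_cfg, seed=seed)

    def fit(self, train_set: list[Pair], val_set: list[Pair] | None = None,
            train_cfg: TrainConfig | None = None,
            loss_cfg: LossConfig | None = None,
            verbose: bool = False) -> FitResult:
        train_cfg = train_cfg or TrainConfig(seed=self.seed)
        loss_cfg = loss_cfg or LossConfig(
            n_classes=self.network_cfg.n_classes)
        self.model, history = train(self.model, train_set, val_set,
                                    train_cfg, loss_cfg, verbose=verbose)
        val = history.to_frame()["val_miou"]
        best = float(np.nanmax(val)) if np.isfinite(val).any() else float("nan")
        return FitResult(self.model, history, train_cfg, loss_cfg, best)

    def save(self, path) -> None:
        save_checkpoint(self.model, path)

    @classmethod
    def load(cls, path) -> "CardiacSegmenter":
        model = load_checkpoint(path)
        obj = cls.__new__(cls)
        obj.network_cfg = model.cfg
        obj.seed = 0
        obj.model = model
        return obj
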