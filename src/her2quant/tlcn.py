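"""Tile-level classification: dataset container, SGD training loop,
prediction, and Monte-Carlo cross-validation.

Training follows the fixed recipe (SGD + momentum, cross-entropy, cosine
learning-rate decay, weight decay) and is bit-reproducible under its seed:
the only randomness is weight initialisation and epoch shuffling, both drawn
from the seeded generator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .backbone import TileClassifier, build_model
from .config import TILE_CLASSES, ModelConfig, TrainConfig
from .errors import ConfigurationError, DataError
from .nn import SGD, cosine_lr, cross_entropy, softmax

TILE_SHAPE = (256, 256, 3)


@dataclass
class TileDataset:
    """In-memory tile collection with labels, source slides and split tags."""

    images: np.ndarray  # [n, 256, 256, 3] uint8
    labels: np.ndarray  # [n] object (class names)
    slide_ids: np.ndarray  # [n] object
    splits: np.ndarray  # [n] object in {train, val, test}

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=object)
        self.slide_ids = np.asarray(self.slide_ids, dtype=object)
        self.splits = np.asarray(self.splits, dtype=object)
        n = len(self.images)
        if not (len(self.labels) == len(self.slide_ids) == len(self.splits) == n):
            raise DataError("images, labels, slide_ids and splits must align")
        if self.images.ndim != 4 or self.images.shape[1:] != TILE_SHAPE:
            raise DataError(
                f"tiles must be {TILE_SHAPE[0]}x{TILE_SHAPE[1]}x3, got {self.images.shape[1:]}"
            )
        bad = set(self.labels) - set(TILE_CLASSES)
        if bad:
            raise DataError(f"unknown tile labels: {sorted(map(str, bad))}")
        bad = set(self.splits) - {"train", "val", "test"}
        if bad:
            raise DataError(f"unknown split tags: {sorted(map(str, bad))}")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, split: str) -> "TileDataset":
        mask = self.splits == split
        return TileDataset(
            self.images[mask], self.labels[mask], self.slide_ids[mask], self.splits[mask]
        )

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "TileDataset":
        """Load from a ``path,label,slide_id,split`` CSV; paths are relative
        to the manifest's directory."""
        import imageio.v3 as iio

        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path)
        required = {"path", "label", "slide_id", "split"}
        if not required.issubset(df.columns):
            raise DataError(f"manifest must have columns {sorted(required)}")
        images = []
        for rel in df["path"]:
            img = np.asarray(iio.imread(manifest_path.parent / rel))
            images.append(img)
        return cls(
            images=np.stack(images),
            labels=df["label"].to_numpy(dtype=object),
            slide_ids=df["slide_id"].to_numpy(dtype=object),
            splits=df["split"].to_numpy(dtype=object),
        )

    def to_manifest(self, out_dir: str | Path) -> Path:
        """Write tiles as PNGs plus a manifest CSV; returns the CSV path."""
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(len(self)):
            rel = f"tile_{i:05d}.png"
            iio.imwrite(out_dir / rel, self.images[i])
            rows.append(
                {
                    "path": rel,
                    "label": self.labels[i],
                    "slide_id": self.slide_ids[i],
                    "split": self.splits[i],
                }
            )
        csv_path = out_dir / "manifest.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        return csv_path


def preprocess(images: np.ndarray, dtype=np.float32) -> np.ndarray:
    """uint8 HWC tiles -> standardised NCHW float batch."""
    x = images.astype(dtype) / 255.0
    x = (x - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _label_indices(labels: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(TILE_CLASSES)}
    return np.array([lut[lab] for lab in labels], dtype=np.int64)


def _accuracy(model: TileClassifier, images: np.ndarray, y: np.ndarray, batch: int = 64) -> float:
    correct = 0
    for lo in range(0, len(images), batch):
        x = preprocess(images[lo : lo + batch])
        logits = model(x, train=False)
        correct += int((np.argmax(logits, axis=1) == y[lo : lo + batch]).sum())
    return correct / len(images)


def train_tlcn(
    dataset: TileDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[TileClassifier, list[dict]]:
    """Train the six-class tile classifier; returns the best-validation model
    and a per-epoch log of loss, learning rate and validation accuracy."""
    if model_config.n_classes != len(TILE_CLASSES):
        raise ConfigurationError("tile training requires the six-class head")
    train = dataset.subset("train")
    val = dataset.subset("val")
    if len(train) == 0:
        raise DataError("training split is empty")
    present = set(train.labels)
    missing = set(TILE_CLASSES) - present
    if missing:
        raise DataError(f"training split lacks classes: {sorted(missing)}")

    rng = np.random.default_rng(train_config.seed)
    model = build_model(model_config, seed=int(rng.integers(0, 2**31)))
    optimizer = SGD(
        model.parameters(),
        lr=train_config.lr,
        momentum=train_config.momentum,
        weight_decay=train_config.weight_decay,
    )
    y_train = _label_indices(train.labels)
    eval_images = val.images if len(val) else train.images
    eval_y = _label_indices(val.labels) if len(val) else y_train

    log: list[dict] = []
    best_acc, best_state = -1.0, None
    for epoch in range(train_config.epochs):
        lr = (
            cosine_lr(train_config.lr, epoch, train_config.epochs)
            if train_config.lr_schedule == "cosine"
            else train_config.lr
        )
        optimizer.lr = lr
        order = rng.permutation(len(train))
        losses = []
        for lo in range(0, len(order), train_config.batch_size):
            idx = order[lo : lo + train_config.batch_size]
            x = preprocess(train.images[idx])
            logits = model(x, train=True)
            loss, dlogits = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise ConfigurationError(f"training loss diverged at epoch {epoch}")
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        val_acc = _accuracy(model, eval_images, eval_y)
        log.append(
            {
                "epoch": epoch,
                "lr": float(lr),
                "train_loss": float(np.mean(losses)),
                "val_accuracy": float(val_acc),
            }
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = copy.deepcopy(model.state_dict())
    model.load_state_dict(best_state)
    return model, log


def predict_tiles(
    model: TileClassifier, tiles: np.ndarray | TileDataset, batch: int = 64
) -> tuple[list[str], np.ndarray]:
    """Per-tile predicted class and softmax probability vectors.

    Ties in the argmax break toward the lowest class index in the canonical
    order (0, 1+, 2+, 3+, normal, noise).
    """
    images = tiles.images if isinstance(tiles, TileDataset) else np.asarray(tiles)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1:] != TILE_SHAPE:
        raise DataError(f"tiles must be {TILE_SHAPE}, got {images.shape[1:]}")
    probs = []
    for lo in range(0, len(images), batch):
        logits = model(preprocess(images[lo : lo + batch]), train=False)
        probs.append(softmax(logits, axis=1))
    probs = np.concatenate(probs) if probs else np.zeros((0, len(TILE_CLASSES)))
    classes = [TILE_CLASSES[i] for i in np.argmax(probs, axis=1)]
    return classes, probs


def evaluate_tlcn(model: TileClassifier, dataset: TileDataset, split: str = "test") -> dict:
    """Six-class metrics (and the merged clinical view) on one split."""
    part = dataset.subset(split)
    if len(part) == 0:
        raise DataError(f"split {split!r} is empty")
    pred, _ = predict_tiles(model, part)
    report = {"six_class": _metrics.evaluate(list(part.labels), pred, TILE_CLASSES)}
    # scored-class views are conditioned on both truth and prediction being scored
    scored = set(("0", "1+", "2+", "3+"))
    tumor_mask = np.array([t in scored and p in scored for t, p in zip(part.labels, pred)])
    if tumor_mask.any():
        yt = [t for t, m in zip(part.labels, tumor_mask) if m]
        yp = [p for p, m in zip(pred, tumor_mask) if m]
        report["four_class"] = _metrics.evaluate(yt, yp, ("0", "1+", "2+", "3+"))
        report["three_class"] = _metrics.evaluate(
            _metrics.merge_classes(yt),
            _metrics.merge_classes(yp),
            ("Negative", "Equivocal", "Positive"),
        )
    return report


def mc_cross_validate(
    dataset: TileDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    n_rounds: int = 5,
    split_ratio: tuple[int, int, int] = (8, 1, 1),
) -> dict:
    """Monte-Carlo cross-validation: repeated independent random splits.

    Each round redraws an 8:1:1 (by default) tile-level split, trains from
    scratch, and evaluates on that round's test split. Reports mean and
    population standard deviation per macro metric plus overall accuracy.
    """
    if n_rounds < 1:
        raise ConfigurationError("n_rounds must be >= 1")
    total = sum(split_ratio)
    per_round: list[dict[str, float]] = []
    for r in range(n_rounds):
        rng = np.random.default_rng([train_config.seed, r])
        order = rng.permutation(len(dataset))
        n_train = int(len(dataset) * split_ratio[0] / total)
        n_val = int(len(dataset) * split_ratio[1] / total)
        splits = np.empty(len(dataset), dtype=object)
        splits[order[:n_train]] = "train"
        splits[order[n_train : n_train + n_val]] = "val"
        splits[order[n_train + n_val :]] = "test"
        ds = TileDataset(dataset.images, dataset.labels, dataset.slide_ids, splits)
        round_cfg = TrainConfig(**{**train_config.to_dict(), "seed": int(rng.integers(0, 2**31))})
        model, _ = train_tlcn(ds, model_config, round_cfg)
        report = evaluate_tlcn(model, ds, "test")
        row = dict(report["six_class"]["macro"])
        row["overall_accuracy"] = report["six_class"]["overall_accuracy"]
        per_round.append(row)
    keys = per_round[0].keys()
    return {
        k: {
            "mean": float(np.mean([row[k] for row in per_round])),
            "std": float(np.std([row[k] for row in per_round])),  # population std
        }
        for k in keys
    } | {"n_rounds": n_rounds}
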