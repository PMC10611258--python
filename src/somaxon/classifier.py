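"""Per-tile toxicity classifiers for the two compartments.

Each compartment gets its own binary classifier ("is this tile from a
damaged culture?"). Labels are weak: every tile of an image inherits the
image's compound-level label (negative for vehicle/negative compounds,
positive for toxicants), so background tiles carry label noise on both
sides - the aggregation statistic downstream is designed to tolerate it.

Tiles are block-mean downsampled to a fixed network input side (48 px) and
scaled to [0, 1] by the 16-bit maximum before entering the CNN, making the
model independent of the image scale factor as long as the tile side is a
multiple of 48.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, TrainingError, UsageError
from .images import BIT_DEPTH_MAX, AreaImage, Tile
from .nn import SmallCNN
from .phenotypes import AreaKind
from .tiling import (axon_tile_side, soma_tile_side, split_soma_local_image,
                     tile_image)

LABELS = ("negative", "positive")


@dataclass(frozen=True)
class TilePrediction:
    """Per-tile positive probability and binary call."""

    parent_id: str
    origin_x: int
    origin_y: int
    positive_probability: float
    positive_call: bool


@dataclass
class TileDataset:
    """Labelled tiles plus the per-condition accounting used for training."""

    tiles: np.ndarray          # (N, side, side) uint16
    labels: np.ndarray         # (N,) int64, 1 = positive
    area_kind: AreaKind
    tile_side: int
    manifest: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        return {"negative": int((self.labels == 0).sum()),
                "positive": int((self.labels == 1).sum())}

    def __len__(self) -> int:
        return len(self.labels)


def tiles_for_image(image: AreaImage) -> list[Tile]:
    """Apply the compartment's tiling scheme to one local image.

    Soma images are first split into 4 quadrant segments, each tiled into
    a 6x6 grid; axon images are tiled directly into a 4x4 grid.
    """
    if image.area_kind == "soma":
        out: list[Tile] = []
        for seg in split_soma_local_image(image):
            out.extend(tile_image(seg, soma_tile_side(seg.width)))
        return out
    return tile_image(image, axon_tile_side(image.width))


def build_training_set(images: Sequence[AreaImage], area_kind: AreaKind,
                       label_map: Mapping[str, str]) -> TileDataset:
    """Weak-label every tile of every training image with its compound class."""
    if not images:
        warnings.warn("empty image collection: returning empty tile set")
        return TileDataset(np.zeros((0, 1, 1), np.uint16), np.zeros(0, np.int64),
                           area_kind, 0)
    tiles: list[np.ndarray] = []
    labels: list[int] = []
    per_condition: dict[tuple[str, str], int] = {}
    tile_side = None
    for img in images:
        if img.area_kind != area_kind:
            raise UsageError(
                f"image {img.image_id!r} is {img.area_kind}, expected {area_kind}")
        if img.split != "train":
            raise UsageError(f"image {img.image_id!r} is not in the train split")
        if img.compound not in label_map:
            raise ConfigurationError(
                f"compound {img.compound!r} missing from label map")
        y = LABELS.index(label_map[img.compound])
        for t in tiles_for_image(img):
            if tile_side is None:
                tile_side = t.side
            elif t.side != tile_side:
                raise UsageError("images produce inconsistent tile sides")
            tiles.append(t.pixels)
            labels.append(y)
        key = img.condition
        per_condition[key] = per_condition.get(key, 0) + 1
    manifest = [(c, conc, n) for (c, conc), n in sorted(per_condition.items())]
    return TileDataset(np.stack(tiles), np.asarray(labels, np.int64),
                       area_kind, int(tile_side), manifest)


def preprocess_tiles(tiles: np.ndarray, input_side: int) -> np.ndarray:
    """uint16 (N, side, side) -> float32 (N, 1, input_side, input_side)."""
    tiles = np.asarray(tiles)
    side = tiles.shape[-1]
    if side % input_side != 0:
        raise UsageError(
            f"tile side {side} is not a multiple of network input {input_side}")
    f = side // input_side
    x = tiles.reshape(-1, input_side, f, input_side, f).mean(axis=(2, 4))
    return (x[:, None, :, :] / BIT_DEPTH_MAX).astype(np.float32)


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are desk-scale and deterministic."""

    epochs: int = 8
    batch_size: int = 128
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    class_weight: str = "none"      # "none" | "balanced"
    augment: bool = False
    channels: tuple[int, int, int, int] = (8, 16, 32, 32)
    input_side: int = 48
    decision_threshold: float = 0.5


@dataclass
class TrainedTileModel:
    """A trained per-tile classifier with its provenance metadata."""

    area_kind: AreaKind
    tile_side: int
    input_side: int
    decision_threshold: float
    train_seed: int
    training_manifest: list
    net: SmallCNN
    val_accuracy: float | None = None

    # ----------------------------------------------------------- inference
    def predict_proba_tiles(self, tiles: np.ndarray) -> np.ndarray:
        """Positive-class probability for raw uint16 tiles (N, side, side)."""
        x = preprocess_tiles(tiles, self.input_side)
        return self.net.predict_proba(x)[:, 1]

    # ------------------------------------------------- Grad-CAM protocol
    def feature_maps(self, tile_pixels: np.ndarray) -> np.ndarray:
        """Final conv activation grid (C, h, w) for one raw tile."""
        x = preprocess_tiles(tile_pixels[None], self.input_side)
        return self.net.feature_maps(x)[0]

    def activation_gradient(self, class_explained: str,
                            grid_shape: tuple) -> np.ndarray:
        if class_explained not in LABELS:
            raise UsageError(f"unknown class {class_explained!r}")
        return self.net.activation_gradient(LABELS.index(class_explained),
                                            grid_shape)

    # ----------------------------------------------------------- serialize
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "area_kind": self.area_kind,
            "tile_side": self.tile_side,
            "input_side": self.input_side,
            "decision_threshold": self.decision_threshold,
            "train_seed": self.train_seed,
            "training_manifest": self.training_manifest,
            "val_accuracy": self.val_accuracy,
        }
        state = self.net.state_dict()
        np.savez(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedTileModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            state = {k: z[k] for k in z.files if k != "meta"}
        net = SmallCNN.from_state_dict(state)
        return cls(area_kind=meta["area_kind"], tile_side=meta["tile_side"],
                   input_side=meta["input_side"],
                   decision_threshold=meta["decision_threshold"],
                   train_seed=meta["train_seed"],
                   training_manifest=[tuple(m) for m in meta["training_manifest"]],
                   net=net, val_accuracy=meta["val_accuracy"])

    def serialized_bytes(self) -> bytes:
        buf = io.BytesIO()
        np.savez(buf, **self.net.state_dict())
        return buf.getvalue()


def train(dataset: TileDataset, seed: int = 0,
          config: TrainConfig | None = None) -> TrainedTileModel:
    """Train a tile classifier; deterministic given (dataset, seed, config)."""
    config = config or TrainConfig()
    counts = dataset.class_counts
    if counts["negative"] == 0 or counts["positive"] == 0:
        raise TrainingError(
            f"both classes required for training, got counts {counts}")
    x = preprocess_tiles(dataset.tiles, config.input_side)
    y = dataset.labels

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    n_val = int(round(config.val_fraction * len(y)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0 or len(np.unique(y[tr_idx])) < 2:
        raise TrainingError("training split lost a class; provide more tiles")

    weights = None
    if config.class_weight == "balanced":
        freq = np.bincount(y[tr_idx], minlength=2).astype(np.float64)
        weights = (len(tr_idx) / (2.0 * np.maximum(freq, 1))).astype(np.float32)
    elif config.class_weight != "none":
        raise ConfigurationError(f"unknown class_weight {config.class_weight!r}")

    net = SmallCNN(channels=config.channels, input_side=config.input_side,
                   n_classes=2, seed=seed)
    net.fit(x[tr_idx], y[tr_idx], epochs=config.epochs,
            batch_size=config.batch_size, lr=config.learning_rate,
            seed=seed + 1, class_weights=weights, augment=config.augment)

    val_acc = None
    if n_val > 0:
        proba = net.predict_proba(x[val_idx])[:, 1]
        val_acc = float(((proba >= config.decision_threshold).astype(int)
                         == y[val_idx]).mean())
    return TrainedTileModel(
        area_kind=dataset.area_kind, tile_side=dataset.tile_side,
        input_side=config.input_side,
        decision_threshold=config.decision_threshold, train_seed=seed,
        training_manifest=dataset.manifest, net=net, val_accuracy=val_acc)


def predict_tiles(model: TrainedTileModel, image: AreaImage) -> list[TilePrediction]:
    """One prediction per tile of ``image``, in row-major tile order."""
    if image.area_kind != model.area_kind:
        raise UsageError(
            f"model is for {model.area_kind}, image is {image.area_kind}")
    tiles = tile_image(image, model.tile_side)
    proba = model.predict_proba_tiles(np.stack([t.pixels for t in tiles]))
    return [
        TilePrediction(parent_id=t.parent_id, origin_x=t.origin_x,
                       origin_y=t.origin_y, positive_probability=float(p),
                       positive_call=bool(p >= model.decision_threshold))
        for t, p in zip(tiles, proba)
    ]
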