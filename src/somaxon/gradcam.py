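"""Grad-CAM attention maps for tile-level decisions.

The map for a chosen class is the rectified, gradient-weighted sum of the
final convolution layer's activation channels: channel weights are the
spatial means of d(logit_class)/d(activation), the weighted sum is passed
through ReLU, upsampled to the tile size and min-max normalized (an
all-constant raw map yields an all-zero map with a warning).

Upsampling is piecewise-linear (separable triangular interpolation
aligned to activation-cell centers). Unlike a plain bilinear resize,
this keeps each activation's exact value at its cell center, so the
relevance peak of the upsampled map always falls inside the activation
cell with maximal raw relevance - a property the tests rely on.

Any model exposing ``feature_maps(tile_pixels) -> (C, h, w)`` and
``activation_gradient(class, (C, h, w)) -> (C, h, w)`` can be explained;
the trained tile classifier implements this protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .images import BIT_DEPTH_MAX, Tile

ClassName = Literal["negative", "positive"]

#: Fig-style palette: blue marks negative-class focus, magenta damage focus.
PALETTE = {"negative": (0.1, 0.3, 1.0), "positive": (1.0, 0.0, 1.0)}


@dataclass(frozen=True)
class AttentionMap:
    """Per-pixel relevance aligned to one tile, normalized to [0, 1]."""

    values: np.ndarray
    class_explained: ClassName
    tile: Tile

    def __post_init__(self) -> None:
        if self.values.shape != self.tile.pixels.shape:
            raise ValueError("attention map must match the tile's extent")


def _upsample_linear(raw: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Cell-center-aligned piecewise-linear upsampling of an activation grid."""
    fy, fx = shape[0] // raw.shape[0], shape[1] // raw.shape[1]
    if shape != (raw.shape[0] * fy, raw.shape[1] * fx):
        raise ValueError(f"tile shape {shape} not a multiple of grid {raw.shape}")
    up = np.repeat(np.repeat(raw, fy, axis=0), fx, axis=1)

    def triangle(f):
        half = f // 2
        k = np.concatenate([np.arange(1, half + 1), np.arange(half - 1, 0, -1)])
        return k / k.sum()

    if fy > 1:
        up = convolve1d(up, triangle(fy), axis=0, mode="nearest")
    if fx > 1:
        up = convolve1d(up, triangle(fx), axis=1, mode="nearest")
    return up


def gradcam(model, tile: Tile, class_explained: ClassName) -> AttentionMap:
    """Compute the Grad-CAM attention map of ``tile`` for one class."""
    acts = np.asarray(model.feature_maps(tile.pixels), dtype=np.float64)
    grads = np.asarray(model.activation_gradient(class_explained, acts.shape),
                       dtype=np.float64)
    alpha = grads.mean(axis=(1, 2))                    # channel weights
    raw = np.maximum(np.tensordot(alpha, acts, axes=1), 0.0)
    if np.ptp(raw) == 0.0:
        warnings.warn("constant Grad-CAM map; returning all zeros")
        values = np.zeros(tile.pixels.shape)
    else:
        up = _upsample_linear(raw, tile.pixels.shape)
        values = (up - up.min()) / (up.max() - up.min())
    return AttentionMap(values=values, class_explained=class_explained,
                        tile=tile)


def overlay(amap: AttentionMap, tile: Tile | None = None,
            palette: dict | None = None) -> np.ndarray:
    """Blend the attention map over the tile; returns an RGB uint8 image.

    The blend weight equals the relevance, so zero relevance reproduces
    the grayscale tile exactly and full relevance takes the pure palette
    color.
    """
    tile = tile if tile is not None else amap.tile
    if amap.values.shape != tile.pixels.shape:
        raise ValueError("map and tile are not aligned")
    palette = palette or PALETTE
    color = np.asarray(palette[amap.class_explained], dtype=np.float64)
    base = (tile.pixels / BIT_DEPTH_MAX)[..., None].repeat(3, axis=-1)
    v = amap.values[..., None]
    out = base * (1.0 - v) + color * v
    return (np.clip(out, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def save_overlays(model, tiles: Sequence[Tile], class_explained: ClassName,
                  out_dir: str | Path) -> list[Path]:
    """Render and save one overlay PNG (plus raw map TIFF) per tile."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tiles:
        amap = gradcam(model, t, class_explained)
        stem = f"{t.parent_id}_x{t.origin_x}_y{t.origin_y}_{class_explained}"
        png = out_dir / f"{stem}.png"
        iio.imwrite(png, overlay(amap))
        tifffile.imwrite(out_dir / f"{stem}_map.tif",
                         amap.values.astype(np.float32))
        paths.append(png)
    return paths
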