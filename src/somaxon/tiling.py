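"""Tiling schemes for local images.

Two schemes are used, mirroring how the two compartments are scored:

* soma: the square local image is first split into its 4 equal quadrants
  ("segments"); each segment is then tiled (tile side = segment side / 6,
  i.e. 36 tiles per segment at any scale);
* axon: the local image is tiled directly into a 4 x 4 grid of tiles.

Tiles are non-overlapping, cover the parent exactly, and are emitted in
row-major order with 0-based top-left-origin coordinates, so reassembly
is bit-exact.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import TilingError, UsageError
from .images import AreaImage, Tile

#: Full-scale reference geometry: local image side, soma tile side, axon tile side.
BASE_IMAGE_SIDE = 2304
BASE_SOMA_TILE_SIDE = 192
BASE_AXON_TILE_SIDE = 576


def split_soma_local_image(image: AreaImage) -> list[AreaImage]:
    """Split a square soma local image into its 4 equal quadrants.

    Quadrants are ordered row-major (top-left, top-right, bottom-left,
    bottom-right); metadata is inherited with the quadrant index appended
    to the image id.
    """
    if image.area_kind != "soma":
        raise UsageError(f"expected a soma image, got {image.area_kind!r}")
    h, w = image.pixels.shape
    if h != w:
        raise TilingError(f"soma local image must be square, got {w}x{h}")
    if h % 2 != 0:
        raise TilingError(f"soma local image side {h} is not divisible by 2")
    half = h // 2
    out = []
    for qi, (r, c) in enumerate(((0, 0), (0, half), (half, 0), (half, half))):
        sub = image.pixels[r:r + half, c:c + half].copy()
        out.append(image.with_pixels(sub, image_id=f"{image.image_id}_q{qi}"))
    return out


def tile_image(image: AreaImage | np.ndarray, side: int,
               parent_id: str | None = None) -> list[Tile]:
    """Cut an image into non-overlapping ``side x side`` tiles, row-major.

    The side must divide both image dimensions exactly; there is no
    padding and no partial tiles.
    """
    if isinstance(image, AreaImage):
        px = image.pixels
        pid = parent_id if parent_id is not None else image.image_id
    else:
        px = np.asarray(image)
        pid = parent_id or ""
    if side < 1:
        raise TilingError(f"tile side must be >= 1, got {side}")
    h, w = px.shape
    if h % side != 0 or w % side != 0:
        raise TilingError(f"tile side {side} does not divide image {w}x{h}")
    tiles = []
    for oy in range(0, h, side):
        for ox in range(0, w, side):
            tiles.append(Tile(
                pixels=px[oy:oy + side, ox:ox + side].copy(),
                origin_x=ox, origin_y=oy, side=side, parent_id=pid,
            ))
    return tiles


def reassemble(tiles: Sequence[Tile], height: int, width: int) -> np.ndarray:
    """Place tiles back by their origins; inverse of :func:`tile_image`."""
    if not tiles:
        raise UsageError("no tiles to reassemble")
    out = np.zeros((height, width), dtype=tiles[0].pixels.dtype)
    for t in tiles:
        out[t.origin_y:t.origin_y + t.side, t.origin_x:t.origin_x + t.side] = t.pixels
    return out


def soma_tile_side(image_width: int) -> int:
    """Tile side for a soma *segment* of the given width (6 tiles per side)."""
    if image_width % 6 != 0:
        raise TilingError(f"soma segment width {image_width} not divisible by 6")
    return image_width // 6


def axon_tile_side(image_width: int) -> int:
    """Tile side for an axon local image of the given width (4 tiles per side)."""
    if image_width % 4 != 0:
        raise TilingError(f"axon image width {image_width} not divisible by 4")
    return image_width // 4
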