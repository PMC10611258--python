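"""Image containers and file IO.

An :class:`AreaImage` is one grayscale local image of either the soma or
the axon compartment, together with the acquisition/treatment metadata the
pipeline needs downstream (compound, concentration, split, replicate).
Images are 16-bit by convention; files go through :mod:`tifffile` /
:mod:`imageio`, manifests through :mod:`pandas`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import DimensionError, UsageError
from .phenotypes import AreaKind, Concentration, Split

BIT_DEPTH_MAX = 65535  # 16-bit full scale


@dataclass
class AreaImage:
    """One compartment-labelled grayscale local image."""

    pixels: np.ndarray
    area_kind: AreaKind
    compound: str = ""
    concentration: Concentration | None = None
    split: Split | None = None
    replicate: int | None = None
    image_id: str = ""
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DimensionError(f"pixels must be 2D, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"non-positive image dimensions {px.shape}")
        if px.dtype != np.uint16:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= BIT_DEPTH_MAX:
                px = px.astype(np.uint16)
            else:
                raise DimensionError(
                    f"pixels must be uint16 within [0, {BIT_DEPTH_MAX}], got {px.dtype}"
                )
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def with_pixels(self, pixels: np.ndarray, image_id: str | None = None) -> "AreaImage":
        out = dataclasses.replace(self, pixels=pixels)
        if image_id is not None:
            out.image_id = image_id
        return out

    @property
    def condition(self) -> tuple[str, str]:
        conc = self.concentration.label if self.concentration else ""
        return (self.compound, conc)


@dataclass(frozen=True)
class Tile:
    """One non-overlapping square patch of a parent image.

    ``origin_x``/``origin_y`` are 0-based pixel offsets of the tile's
    top-left corner in the parent (top-left origin).
    """

    pixels: np.ndarray
    origin_x: int
    origin_y: int
    side: int
    parent_id: str

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.side, self.side):
            raise DimensionError(
                f"tile pixels {self.pixels.shape} do not match side {self.side}"
            )


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def write_image(image: AreaImage, path: str | Path) -> Path:
    """Write a 16-bit grayscale TIFF (or PNG if the suffix says so)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, image.pixels)
    else:
        raise UsageError(f"unsupported image suffix {path.suffix!r}")
    return path


def read_image(path: str | Path, area_kind: AreaKind, **meta) -> AreaImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    if px.ndim == 3:  # multi-channel: keep the configured fluorescence channel
        px = px[..., int(meta.pop("channel", 0))]
    return AreaImage(pixels=np.asarray(px, dtype=np.uint16), area_kind=area_kind,
                     image_id=meta.pop("image_id", path.stem), **meta)


MANIFEST_COLUMNS = [
    "image_id", "compound", "concentration", "unit", "area_kind",
    "split", "replicate", "seed", "path",
]


def manifest_frame(images: Sequence[AreaImage], paths: Sequence[str | Path] | None = None) -> pd.DataFrame:
    rows = []
    for i, img in enumerate(images):
        rows.append({
            "image_id": img.image_id,
            "compound": img.compound,
            "concentration": img.concentration.value if img.concentration else np.nan,
            "unit": img.concentration.unit if img.concentration else "",
            "area_kind": img.area_kind,
            "split": img.split,
            "replicate": img.replicate,
            "seed": img.seed,
            "path": str(paths[i]) if paths is not None else "",
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def save_study(images: Sequence[AreaImage], out_dir: str | Path,
               fmt: str = "tif") -> pd.DataFrame:
    """Write one image file per AreaImage plus a sidecar manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in images:
        p = out_dir / f"{img.image_id}.{fmt}"
        write_image(img, p)
        paths.append(p)
    manifest = manifest_frame(images, paths)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_study(manifest_csv: str | Path) -> list[AreaImage]:
    manifest = pd.read_csv(manifest_csv)
    base = Path(manifest_csv).parent
    images = []
    for row in manifest.itertuples(index=False):
        conc = None
        if not pd.isna(row.concentration):
            conc = Concentration(float(row.concentration), str(row.unit))
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        images.append(read_image(
            p, area_kind=row.area_kind, image_id=row.image_id,
            compound=row.compound, concentration=conc, split=row.split,
            replicate=None if pd.isna(row.replicate) else int(row.replicate),
            seed=None if pd.isna(row.seed) else int(row.seed),
        ))
    return images
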