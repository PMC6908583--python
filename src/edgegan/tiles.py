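"""The labelled tile container and PNG/manifest I/O helpers."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidArgumentError

__all__ = ["Tile", "stack_pixels", "load_image", "save_image", "read_manifest"]


@dataclass
class Tile:
    """An 8-bit RGB patch with optional label and provenance coordinates.

    ``row``/``col`` are the 0-based top-left pixel coordinates of the tile
    in its source image, when the tile was cut from one.
    """

    pixels: np.ndarray
    label: str | None = None
    source_id: str | None = None
    row: int | None = None
    col: int | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidArgumentError(f"tile pixels must be H x W x 3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise InvalidArgumentError(f"tile pixels must be uint8, got {self.pixels.dtype}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def stack_pixels(tiles: list[Tile]) -> np.ndarray:
    """Stack equally sized tiles into an (N, H, W, 3) uint8 array."""
    return np.stack([t.pixels for t in tiles])


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or TIFF); alpha channels are rejected."""
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidArgumentError(
            f"{path}: expected an RGB image, got shape {arr.shape}"
        )
    return np.asarray(arr, dtype=np.uint8)


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    iio.imwrite(path, pixels)


def read_manifest(manifest_path: str | Path) -> list[Tile]:
    """Load tiles listed in a ``manifest.csv`` (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    tiles: list[Tile] = []
    with open(manifest_path, newline="") as fh:
        for rec in csv.DictReader(fh):
            tiles.append(
                Tile(
                    pixels=load_image(base / rec["path"]),
                    label=rec.get("label") or None,
                    source_id=rec.get("source_id") or None,
                    row=int(rec["row"]) if rec.get("row") not in (None, "") else None,
                    col=int(rec["col"]) if rec.get("col") not in (None, "") else None,
                )
            )
    return tiles
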