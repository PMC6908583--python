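"""Stereology grid sampling of tiles from an annotated image.

A square grid of points is laid across the image; each point is the
top-left corner (0-based) of a half-open ``[r, r+T) x [c, c+T)`` square,
and the square is emitted as a tile only if it lies entirely inside the
annotation mask.  Grid spacing defaults to the tile size (non-overlapping
tiles); a containment-fraction knob below 1.0 relaxes the all-pixels rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConflictError, InvalidArgumentError
from .tiles import Tile, save_image

__all__ = ["AnnotationMask", "StereologyGrid", "stereology_sample", "write_tileset"]


@dataclass
class AnnotationMask:
    """A binary mask aligned to a source image, carrying its class label."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise InvalidArgumentError(f"mask must be 2-D, got shape {self.mask.shape}")
        self.mask = self.mask.astype(bool)


@dataclass(frozen=True)
class StereologyGrid:
    """Square point grid: tile size, spacing between points, and the
    (row, col) offset of the first point."""

    tile_size: int = 256
    spacing: int | None = None  # None -> tile_size (non-overlapping)
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise InvalidArgumentError(f"tile_size must be >= 1, got {self.tile_size}")
        if self.spacing is not None and self.spacing < 1:
            raise InvalidArgumentError(f"spacing must be >= 1, got {self.spacing}")
        if self.offset[0] < 0 or self.offset[1] < 0:
            raise InvalidArgumentError(f"offset must be >= (0, 0), got {self.offset}")

    @property
    def step(self) -> int:
        return self.tile_size if self.spacing is None else self.spacing


def stereology_sample(image: np.ndarray, mask: AnnotationMask, grid: StereologyGrid,
                      min_containment: float = 1.0, source_id: str | None = None) -> list[Tile]:
    """Extract grid squares strictly inside the annotation as labelled tiles.

    With the default ``min_containment=1.0`` a square is kept only if every
    one of its pixels is inside the mask.  Tiles carry the (row, col) of
    their top-left corner and the mask's label.  Deterministic.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidArgumentError(f"expected an (H, W, 3) image, got {image.shape}")
    if mask.mask.shape != image.shape[:2]:
        raise InvalidArgumentError(
            f"mask shape {mask.mask.shape} does not match image {image.shape[:2]}"
        )
    if not 0.0 < min_containment <= 1.0:
        raise InvalidArgumentError(f"min_containment must be in (0, 1], got {min_containment}")
    t = grid.tile_size
    h, w = mask.mask.shape
    # summed-area table for fast containment counts
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask.mask, axis=0), axis=1, out=sat[1:, 1:])
    need = min_containment * t * t
    tiles: list[Tile] = []
    for r in range(grid.offset[0], h - t + 1, grid.step):
        for c in range(grid.offset[1], w - t + 1, grid.step):
            inside = sat[r + t, c + t] - sat[r, c + t] - sat[r + t, c] + sat[r, c]
            if inside >= need:
                tiles.append(Tile(pixels=image[r:r + t, c:c + t].copy(),
                                  label=mask.label, source_id=source_id, row=r, col=c))
    return tiles


def write_tileset(tiles: list[Tile], out_dir: str | Path) -> Path:
    """Write tiles as PNGs plus a ``manifest.csv``; returns the manifest path.

    Refuses to overwrite an existing manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    if manifest.exists():
        raise ConflictError(f"{manifest} already exists; refusing to overwrite")
    counters: dict[str, int] = {}
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "source_id", "row", "col", "tile_size"])
        for tile in tiles:
            label = tile.label or "unlabeled"
            idx = counters.get(label, 0)
            counters[label] = idx + 1
            name = f"{label}_{idx:05d}.png"
            save_image(out / name, tile.pixels)
            writer.writerow([name, label, tile.source_id or "",
                             "" if tile.row is None else tile.row,
                             "" if tile.col is None else tile.col,
                             tile.size])
    return manifest
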