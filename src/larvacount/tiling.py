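"""Fixed (sequential, non-overlapping) segmentation of an image into tiles.

The grid starts at the upper-left corner and proceeds row-major.  Interior
tiles are ``tile_size x tile_size``; the last row/column keep their true
remainder size, so the tiles partition the image exactly — every pixel
belongs to exactly one tile and no pixel is padded or resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, Tuple

import numpy as np

from .boxes import Box


@dataclass(frozen=True, slots=True)
class Tile:
    """One cell of the fixed segmentation, in global pixel coordinates."""

    row: int
    col: int
    origin: Tuple[int, int]  # (x, y) of the upper-left corner
    width_px: int
    height_px: int

    @property
    def bounds(self) -> Box:
        x0, y0 = self.origin
        return Box(x0, y0, x0 + self.width_px, y0 + self.height_px)


@dataclass(frozen=True)
class TileGrid:
    tile_size: int
    image_width: int
    image_height: int
    tiles: Tuple[Tile, ...]  # row-major

    @property
    def n_cols(self) -> int:
        return math.ceil(self.image_width / self.tile_size)

    @property
    def n_rows(self) -> int:
        return math.ceil(self.image_height / self.tile_size)

    def tile_at(self, row: int, col: int) -> Tile:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"tile ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return self.tiles[row * self.n_cols + col]

    def __iter__(self) -> Iterator[Tile]:
        return iter(self.tiles)

    def __len__(self) -> int:
        return len(self.tiles)


def segment_image(image_width: int, image_height: int, tile_size: int) -> TileGrid:
    """Partition an ``image_width x image_height`` raster into a fixed grid.

    ``n_cols = ceil(image_width / tile_size)``; the last column's width is
    ``image_width - (n_cols - 1) * tile_size`` (and analogously for rows), so
    edge tiles keep their true size rather than being padded.
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1, got {tile_size}")
    if image_width < 1 or image_height < 1:
        raise ValueError(f"image dimensions must be >= 1, got {image_width}x{image_height}")
    n_cols = math.ceil(image_width / tile_size)
    n_rows = math.ceil(image_height / tile_size)
    tiles: List[Tile] = []
    for row in range(n_rows):
        y0 = row * tile_size
        h = min(tile_size, image_height - y0)
        for col in range(n_cols):
            x0 = col * tile_size
            w = min(tile_size, image_width - x0)
            tiles.append(Tile(row=row, col=col, origin=(x0, y0), width_px=w, height_px=h))
    return TileGrid(
        tile_size=tile_size,
        image_width=image_width,
        image_height=image_height,
        tiles=tuple(tiles),
    )


def crop(image: np.ndarray, tile: Tile) -> np.ndarray:
    """Extract the exact pixel sub-raster of a tile (a view, no resampling)."""
    x0, y0 = tile.origin
    h, w = image.shape[:2]
    if x0 < 0 or y0 < 0 or x0 + tile.width_px > w or y0 + tile.height_px > h:
        raise ValueError(f"tile {tile} out of bounds for image {w}x{h}")
    return image[y0 : y0 + tile.height_px, x0 : x0 + tile.width_px]


def to_global(box: Box, tile: Tile) -> Box:
    """Translate a tile-local box into global image coordinates."""
    if box.x_min < 0 or box.y_min < 0 or box.x_max > tile.width_px or box.y_max > tile.height_px:
        raise ValueError(f"box {box} outside tile-local bounds {tile.width_px}x{tile.height_px}")
    return box.translate(*tile.origin)


def to_local(box: Box, tile: Tile) -> Box:
    """Inverse of :func:`to_global`."""
    x0, y0 = tile.origin
    local = box.translate(-x0, -y0)
    if (
        local.x_min < 0
        or local.y_min < 0
        or local.x_max > tile.width_px
        or local.y_max > tile.height_px
    ):
        raise ValueError(f"box {box} not contained in tile {tile}")
    return local
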