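"""Square tiling of large rasters and box coordinate transforms.

Boxes are axis-aligned, 0-based and half-open: a :class:`PixelBox` with
``x_min=10, x_max=13`` covers pixel columns 10, 11 and 12.  This makes
areas and intersections exact integer arithmetic and the tiling a true
partition of the padded image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

import numpy as np

__all__ = [
    "PixelBox",
    "NormalizedBox",
    "TileGrid",
    "plan_tile_grid",
    "pad_to_grid",
    "split_into_tiles",
    "tile_local_to_global",
    "clip_box_to_tile",
]

TileIndex = Tuple[int, int]  # (row, col)


@dataclass(frozen=True)
class PixelBox:
    """Axis-aligned rectangle in pixel coordinates, half-open [min, max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"negative coordinates: {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "PixelBox":
        return PixelBox(self.x_min + dx, self.y_min + dy,
                        self.x_max + dx, self.y_max + dy)

    def intersect(self, other: "PixelBox") -> Optional["PixelBox"]:
        """Intersection box, or None when overlap has zero area."""
        x0 = max(self.x_min, other.x_min)
        y0 = max(self.y_min, other.y_min)
        x1 = min(self.x_max, other.x_max)
        y1 = min(self.y_max, other.y_max)
        if x0 >= x1 or y0 >= y1:
            return None
        return PixelBox(x0, y0, x1, y1)


@dataclass(frozen=True)
class NormalizedBox:
    """Detection label: class id plus center/size as fractions of the image."""

    class_id: int
    x_c: float
    y_c: float
    w: float
    h: float

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (0.0 <= self.x_c <= 1.0 and 0.0 <= self.y_c <= 1.0):
            raise ValueError(f"center outside [0,1]: {self}")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"size outside (0,1]: {self}")
        if (self.x_c - self.w / 2 < -eps or self.x_c + self.w / 2 > 1 + eps
                or self.y_c - self.h / 2 < -eps or self.y_c + self.h / 2 > 1 + eps):
            raise ValueError(f"box extends outside the unit square: {self}")

    @classmethod
    def from_pixel(cls, box: PixelBox, image_width: int, image_height: int,
                   class_id: int = 0) -> "NormalizedBox":
        return cls(
            class_id=class_id,
            x_c=(box.x_min + box.x_max) / 2 / image_width,
            y_c=(box.y_min + box.y_max) / 2 / image_height,
            w=box.width / image_width,
            h=box.height / image_height,
        )

    def to_pixel(self, image_width: int, image_height: int) -> PixelBox:
        w = self.w * image_width
        h = self.h * image_height
        x_c = self.x_c * image_width
        y_c = self.y_c * image_height
        return PixelBox(x_c - w / 2, y_c - h / 2, x_c + w / 2, y_c + h / 2)


@dataclass(frozen=True)
class TileGrid:
    """Tiling plan for one image: tile counts per axis plus edge padding."""

    image_width: int
    image_height: int
    tile_size: int
    n_cols: int
    n_rows: int
    pad_right: int
    pad_bottom: int

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def padded_width(self) -> int:
        return self.n_cols * self.tile_size

    @property
    def padded_height(self) -> int:
        return self.n_rows * self.tile_size

    def tile_box(self, index: TileIndex) -> PixelBox:
        """Pixel extent of one tile in the padded-image frame."""
        row, col = self._check_index(index)
        t = self.tile_size
        return PixelBox(col * t, row * t, (col + 1) * t, (row + 1) * t)

    def indices(self) -> Iterator[TileIndex]:
        """Row-major tile indices from the top-left corner."""
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield (row, col)

    def _check_index(self, index: TileIndex) -> TileIndex:
        row, col = index
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"tile index {index} outside grid {self.n_rows}x{self.n_cols}")
        return row, col


def plan_tile_grid(image_width: int, image_height: int,
                   tile_size: int = 400) -> TileGrid:
    """Plan a square tiling that covers the image, padding right/bottom edges.

    >>> plan_tile_grid(8256, 5504, 400).n_tiles
    294
    """
    for name, v in (("image_width", image_width), ("image_height", image_height),
                    ("tile_size", tile_size)):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    n_cols = math.ceil(image_width / tile_size)
    n_rows = math.ceil(image_height / tile_size)
    return TileGrid(
        image_width=int(image_width),
        image_height=int(image_height),
        tile_size=int(tile_size),
        n_cols=n_cols,
        n_rows=n_rows,
        pad_right=n_cols * tile_size - image_width,
        pad_bottom=n_rows * tile_size - image_height,
    )


def pad_to_grid(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Zero-pad the right and bottom edges so the grid tiles the image exactly.

    The origin stays fixed; original pixels keep their coordinates.
    """
    h, w = image.shape[:2]
    if (w, h) != (grid.image_width, grid.image_height):
        raise ValueError(
            f"image is {w}x{h} but grid was planned for "
            f"{grid.image_width}x{grid.image_height}")
    pad = [(0, grid.pad_bottom), (0, grid.pad_right)]
    pad += [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="constant", constant_values=0)


def split_into_tiles(image: np.ndarray,
                     grid: TileGrid) -> List[Tuple[TileIndex, np.ndarray]]:
    """Cut a padded image into tile_size x tile_size views, row-major order."""
    h, w = image.shape[:2]
    if (w, h) != (grid.padded_width, grid.padded_height):
        raise ValueError(
            f"image is {w}x{h}; expected padded dimensions "
            f"{grid.padded_width}x{grid.padded_height} (pad first)")
    t = grid.tile_size
    out = []
    for row, col in grid.indices():
        out.append(((row, col),
                    image[row * t:(row + 1) * t, col * t:(col + 1) * t]))
    return out


def tile_local_to_global(box: PixelBox, tile_index: TileIndex,
                         grid: TileGrid) -> PixelBox:
    """Translate a tile-local box into padded-image coordinates."""
    row, col = grid._check_index(tile_index)
    return box.translate(col * grid.tile_size, row * grid.tile_size)


def clip_box_to_tile(box: PixelBox, tile_index: TileIndex,
                     grid: TileGrid) -> Optional[PixelBox]:
    """Intersect a global box with one tile and express it tile-locally.

    Returns None when the intersection has zero area.  Objects crossing a
    tile border are therefore clipped into independent per-tile fragments;
    the possible double count at borders is accepted, not corrected.
    """
    row, col = grid._check_index(tile_index)
    inter = box.intersect(grid.tile_box(tile_index))
    if inter is None:
        return None
    return inter.translate(-col * grid.tile_size, -row * grid.tile_size)
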