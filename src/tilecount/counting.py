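"""Per-tile detection with a pluggable detector, confidence filtering, and
per-side / per-plant count aggregation.

A detector is any callable ``detector(tile, tile_index) -> detections``
where ``tile`` is a ``tile_size x tile_size`` raster, ``tile_index`` is the
``(row, col)`` position of the tile in its grid, and each returned detection
carries a tile-local :class:`~tilecount.geometry.PixelBox` and a confidence
in [0, 1].  Counts are the number of detections surviving the confidence
cutoff, summed over tiles — no cross-tile merging and no two-side
deduplication; the resulting bias is handled downstream by calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import (PixelBox, TileGrid, TileIndex, pad_to_grid,
                       plan_tile_grid, split_into_tiles, tile_local_to_global)
from .metrics import Detection

__all__ = [
    "TileDetection",
    "Detector",
    "CountingConfig",
    "SideCount",
    "PlantCount",
    "DetectorContractError",
    "detect_tiles",
    "count_side",
    "count_plant",
]


@dataclass(frozen=True)
class TileDetection:
    """Detector output for one object: tile-local box plus confidence."""

    box: PixelBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence outside [0,1]: {self.confidence}")


Detector = Callable[[np.ndarray, TileIndex], Sequence[TileDetection]]


@dataclass(frozen=True)
class CountingConfig:
    tile_size: int = 400
    confidence_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError(
                f"confidence_threshold must be in [0,1], "
                f"got {self.confidence_threshold}")
        if self.tile_size <= 0:
            raise ValueError(f"tile_size must be positive, got {self.tile_size}")


class DetectorContractError(RuntimeError):
    """Detector returned an out-of-contract detection (names the tile)."""


@dataclass(frozen=True)
class SideCount:
    plant_id: str
    side: str
    detections: Tuple[Detection, ...]
    raw_count: int


@dataclass(frozen=True)
class PlantCount:
    plant_id: str
    side_a: int
    side_b: int
    corrected: Optional[float] = None

    @property
    def raw_total(self) -> int:
        return self.side_a + self.side_b


def _check_contract(dets: Sequence[TileDetection], tile_index: TileIndex,
                    tile_size: int) -> None:
    for d in dets:
        if not 0.0 <= d.confidence <= 1.0:
            raise DetectorContractError(
                f"tile {tile_index}: confidence {d.confidence} outside [0,1]")
        b = d.box
        if b.x_min < 0 or b.y_min < 0 or b.x_max > tile_size or b.y_max > tile_size:
            raise DetectorContractError(
                f"tile {tile_index}: box {b} outside {tile_size}x{tile_size} tile")


def detect_tiles(detector: Detector, image: np.ndarray,
                 config: CountingConfig = CountingConfig(),
                 grid: Optional[TileGrid] = None) -> List[Detection]:
    """Tile the image, run the detector per tile, filter by confidence, and
    map surviving boxes to global (padded-image) coordinates."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if grid is None:
        grid = plan_tile_grid(w, h, config.tile_size)
    padded = pad_to_grid(image, grid)
    out: List[Detection] = []
    for tile_index, tile in split_into_tiles(padded, grid):
        dets = detector(tile, tile_index)
        _check_contract(dets, tile_index, grid.tile_size)
        for d in dets:
            if d.confidence < config.confidence_threshold:
                continue
            out.append(Detection(
                box=tile_local_to_global(d.box, tile_index, grid),
                confidence=d.confidence,
                image_id=0))
    return out


def count_side(detector: Detector, image: np.ndarray,
               config: CountingConfig = CountingConfig(),
               plant_id: str = "", side: str = "a") -> SideCount:
    """Total surviving detections over all tiles of one plant-side image."""
    dets = detect_tiles(detector, image, config)
    return SideCount(plant_id=plant_id, side=side,
                     detections=tuple(dets), raw_count=len(dets))


def count_plant(side_a: SideCount, side_b: SideCount) -> PlantCount:
    """Sum the two side counts; no cross-side deduplication."""
    if side_a.plant_id != side_b.plant_id:
        raise ValueError(
            f"mismatched plant ids: {side_a.plant_id!r} vs {side_b.plant_id!r}")
    return PlantCount(plant_id=side_a.plant_id,
                      side_a=side_a.raw_count, side_b=side_b.raw_count)
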