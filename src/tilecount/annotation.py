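"""Binary masks to normalized bounding-box labels, label-file I/O, and
balanced tile-dataset assembly.

Label files follow the common plain-text detection format: one object per
line, ``class x_c y_c w h`` with the four coordinates normalized to [0, 1]
and printed with six decimals (round-trip stable).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import (NormalizedBox, PixelBox, TileIndex, pad_to_grid,
                       plan_tile_grid, split_into_tiles)

__all__ = [
    "mask_to_boxes",
    "mask_to_pixel_boxes",
    "write_labels",
    "read_labels",
    "TileRecord",
    "DatasetManifest",
    "build_dataset",
]

# 8-connectivity: diagonal pixel chains of tiny blobs stay one component.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

LABEL_PRECISION = 6


class LabelParseError(ValueError):
    """A label file line could not be parsed or validated."""


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be only 0 or 1")
    return mask.astype(bool)


def mask_to_pixel_boxes(mask: np.ndarray,
                        min_area: int = 0) -> List[PixelBox]:
    """Minimal enclosing rectangle of each 8-connected foreground component."""
    m = _validate_mask(mask)
    labeled, n = ndimage.label(m, structure=_STRUCTURE_8)
    boxes: List[PixelBox] = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:
            continue
        ys, xs = sl
        area = int((labeled[sl] > 0).sum())
        if area < min_area:
            continue
        boxes.append(PixelBox(xs.start, ys.start, xs.stop, ys.stop))
    return boxes


def mask_to_boxes(mask: np.ndarray, min_area: int = 0) -> List[NormalizedBox]:
    """One normalized box per connected foreground component (class 0)."""
    mask = np.asarray(mask)
    h, w = mask.shape[:2]
    return [NormalizedBox.from_pixel(b, w, h, class_id=0)
            for b in mask_to_pixel_boxes(mask, min_area=min_area)]


def write_labels(records: Sequence[NormalizedBox], path) -> None:
    """Write one `class x_c y_c w h` line per box; empty list → empty file."""
    lines = [
        f"{r.class_id:d} {r.x_c:.{LABEL_PRECISION}f} {r.y_c:.{LABEL_PRECISION}f} "
        f"{r.w:.{LABEL_PRECISION}f} {r.h:.{LABEL_PRECISION}f}"
        for r in records
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_labels(path) -> List[NormalizedBox]:
    records: List[NormalizedBox] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(
                f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            class_id = int(parts[0])
            x_c, y_c, w, h = map(float, parts[1:])
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from None
        try:
            records.append(NormalizedBox(class_id, x_c, y_c, w, h))
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from None
    return records


@dataclass(frozen=True)
class TileRecord:
    """One tile of one source image, with its labels."""

    tile_id: str
    source_index: int
    tile_index: TileIndex
    boxes: Tuple[NormalizedBox, ...]
    split: str = "train"

    @property
    def n_objects(self) -> int:
        return len(self.boxes)


@dataclass
class DatasetManifest:
    tile_size: int
    target_size: int
    empty_fraction: float
    seed: int
    records: List[TileRecord] = field(default_factory=list)

    @property
    def n_empty(self) -> int:
        return sum(1 for r in self.records if r.n_objects == 0)

    def write_labels(self, directory) -> List[Path]:
        """Write one label file per tile (stem = tile id); returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for rec in self.records:
            p = directory / f"{rec.tile_id}.txt"
            write_labels(rec.boxes, p)
            paths.append(p)
        return paths


class DatasetShortfallError(ValueError):
    """Not enough tiles of the requested kind to assemble the dataset."""


def _tile_all(pairs, tile_size: int) -> List[TileRecord]:
    candidates: List[TileRecord] = []
    for i, (image, mask) in enumerate(pairs):
        image = np.asarray(image)
        mask = np.asarray(mask)
        if image.shape[:2] != mask.shape[:2]:
            raise ValueError(
                f"pair {i}: image {image.shape[:2]} vs mask {mask.shape[:2]}")
        h, w = mask.shape[:2]
        grid = plan_tile_grid(w, h, tile_size)
        padded_mask = pad_to_grid(mask, grid)
        for idx, tile_mask in split_into_tiles(padded_mask, grid):
            boxes = tuple(mask_to_boxes(tile_mask))
            candidates.append(TileRecord(
                tile_id=f"img{i:04d}_r{idx[0]:03d}_c{idx[1]:03d}",
                source_index=i, tile_index=idx, boxes=boxes))
    return candidates


def build_dataset(pairs: Iterable[Tuple[np.ndarray, np.ndarray]],
                  tile_size: int = 400,
                  target_size: int = 2000,
                  empty_fraction: float = 0.30,
                  seed: int = 0,
                  val_fraction: float = 0.20) -> DatasetManifest:
    """Tile image/mask pairs and sample a balanced manifest.

    Exactly ``round(empty_fraction * target_size)`` of the sampled tiles have
    zero objects; sampling is without replacement and deterministic for a
    fixed seed.  A trailing ``val_fraction`` share of the shuffled sample is
    assigned to the validation split.
    """
    if not 0.0 <= empty_fraction <= 1.0:
        raise ValueError("empty_fraction must be in [0, 1]")
    candidates = _tile_all(pairs, tile_size)
    empty = [c for c in candidates if c.n_objects == 0]
    full = [c for c in candidates if c.n_objects > 0]
    n_empty = round(empty_fraction * target_size)
    n_full = target_size - n_empty
    if len(empty) < n_empty or len(full) < n_full:
        raise DatasetShortfallError(
            f"need {n_empty} empty and {n_full} non-empty tiles but only "
            f"{len(empty)} empty and {len(full)} non-empty are available")
    rng = np.random.default_rng(seed)
    chosen = ([empty[i] for i in rng.choice(len(empty), n_empty, replace=False)]
              + [full[i] for i in rng.choice(len(full), n_full, replace=False)])
    order = rng.permutation(len(chosen))
    n_val = round(val_fraction * len(chosen))
    records = []
    for pos, j in enumerate(order):
        rec = chosen[j]
        split = "val" if pos >= len(chosen) - n_val else "train"
        records.append(TileRecord(rec.tile_id, rec.source_index,
                                  rec.tile_index, rec.boxes, split=split))
    return DatasetManifest(tile_size=tile_size, target_size=target_size,
                           empty_fraction=empty_fraction, seed=seed,
                           records=records)
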