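"""Synthetic test scenes, a noise-configurable oracle detector, and
plant-count scenario simulation.

The scenes are not photorealistic — only the statistics that the rest of
the pipeline is sensitive to are emulated: tiny low-contrast elliptical
blobs whose pixel areas concentrate in a narrow band (83% of mass in
[280, 320] px² by default, i.e. roughly 17-20 px across), centroids uniform
over the allowed region, and a cluttered branch-like background.

All randomness flows from the seed carried by each spec; the oracle
detector derives an independent stream per tile so results do not depend
on tile visiting order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .counting import Detector, TileDetection
from .geometry import PixelBox, TileGrid, TileIndex, clip_box_to_tile

__all__ = [
    "SceneSpec",
    "OracleNoise",
    "PlantScenario",
    "PlacementError",
    "generate_scene",
    "make_oracle_detector",
    "simulate_plant_counts",
]


class PlacementError(RuntimeError):
    """Could not place the requested number of blobs after bounded retries."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic plant-side scene."""

    width: int = 1200
    height: int = 800
    n_flowers: int = 50
    # pixel-area mixture: main_fraction of mass uniform on area_main,
    # the rest uniform on the two tail intervals
    area_main: Tuple[float, float] = (280.0, 320.0)
    area_tails: Tuple[Tuple[float, float], ...] = ((150.0, 280.0), (320.0, 500.0))
    main_fraction: float = 0.83
    aspect_range: Tuple[float, float] = (0.75, 1.33)
    n_branches: int = 25
    allow_border: bool = False
    # when set, blobs are kept strictly inside single tiles of this size
    keep_within_tiles: Optional[int] = None
    seed: int = 0


@dataclass(frozen=True)
class OracleNoise:
    """Noise model of the oracle detector.

    Zero everywhere (the default) makes the oracle reproduce the ground
    truth exactly with confidence 1.0.
    """

    miss_rate: float = 0.0          # probability of dropping a true box
    fp_per_tile: float = 0.0        # Poisson mean of spurious boxes per tile
    jitter_px: float = 0.0          # Gaussian sigma of center displacement
    true_conf_range: Tuple[float, float] = (1.0, 1.0)
    fp_conf_range: Tuple[float, float] = (0.5, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError(f"miss_rate outside [0,1]: {self.miss_rate}")
        if self.fp_per_tile < 0 or self.jitter_px < 0:
            raise ValueError("fp_per_tile and jitter_px must be >= 0")


@dataclass(frozen=True)
class PlantScenario:
    """Two-side count scenario with occlusion and double-count bias.

    Each flower is visible (captured by one of the two images) with
    probability ``visible_a + visible_b`` and attributed to a side in
    proportion to the two fractions; a visible flower additionally appears
    on the opposite side — and is therefore counted twice by the pipeline —
    with probability ``double_count``.  With the defaults every flower is
    counted exactly once, so raw totals equal true counts deterministically.

    When ``bias_slope`` is set, the reference (operator) count is generated
    as ``bias_slope * raw_total + bias_intercept + N(0, reference_noise_sd)``
    so that calibration-recovery experiments have a known true line;
    otherwise the reference is the true flower count.
    """

    true_count_range: Tuple[int, int] = (150, 700)
    visible_a: float = 0.5
    visible_b: float = 0.5
    double_count: float = 0.0
    miss_rate: float = 0.0
    fp_per_side: float = 0.0
    bias_slope: Optional[float] = None
    bias_intercept: float = 0.0
    reference_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        va, vb, d = self.visible_a, self.visible_b, self.double_count
        if not (0 <= va <= 1 and 0 <= vb <= 1 and 0 <= d <= 1):
            raise ValueError("visibility fractions must be in [0,1]")
        if va + vb > 1 + 1e-12:
            raise ValueError("visible_a + visible_b must not exceed 1")


# ---------------------------------------------------------------------------
# scene rendering

_BACKGROUND = np.array([74, 66, 58], dtype=np.float32)    # grey-brown
_BRANCH = np.array([96, 78, 60], dtype=np.float32)
_FLOWER = np.array([150, 60, 70], dtype=np.float32)       # dull red


def _sample_area(rng: np.random.Generator, spec: SceneSpec) -> float:
    if rng.random() < spec.main_fraction:
        lo, hi = spec.area_main
    else:
        lo, hi = spec.area_tails[rng.integers(len(spec.area_tails))]
    return float(rng.uniform(lo, hi))


def _ellipse_pixels(cy: float, cx: float, area: float, aspect: float,
                    angle: float, shape) -> Tuple[np.ndarray, np.ndarray]:
    # semi-axes giving the target area for the given aspect ratio
    ry = np.sqrt(area * aspect / np.pi)
    rx = np.sqrt(area / (aspect * np.pi))
    rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=shape, rotation=angle)
    if rr.size:
        # one corrective rescale: discretization error shrinks to ~1-2 px²
        scale = np.sqrt(area / rr.size)
        rr, cc = skdraw.ellipse(cy, cx, ry * scale, rx * scale,
                                shape=shape, rotation=angle)
    return rr, cc


def _crosses_tile_border(box: PixelBox, tile: int) -> bool:
    return (box.x_min // tile != (box.x_max - 1) // tile
            or box.y_min // tile != (box.y_max - 1) // tile)


def _paint_background(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    img = np.ones((spec.height, spec.width, 3), dtype=np.float32) * _BACKGROUND
    # cheap integer speckle instead of Gaussian noise: much faster on large
    # rasters and statistically irrelevant to the test surface
    img += rng.integers(-12, 13, size=img.shape, dtype=np.int8)
    for _ in range(spec.n_branches):
        r0, r1 = rng.integers(0, spec.height, 2)
        c0, c1 = rng.integers(0, spec.width, 2)
        thickness = int(rng.integers(2, 6))
        for off in range(thickness):
            rr, cc = skdraw.line(min(r0 + off, spec.height - 1), c0,
                                 min(r1 + off, spec.height - 1), c1)
            img[rr, cc] = _BRANCH + rng.normal(0, 5, size=3)
    return img


def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, np.ndarray,
                                             List[PixelBox]]:
    """Render a scene; returns (RGB uint8 image, binary mask, true boxes).

    Blobs never touch each other (8-connectivity safe), so the mask has
    exactly ``spec.n_flowers`` connected components and the returned boxes
    are exactly their minimal enclosing rectangles.
    """
    rng = np.random.default_rng(spec.seed)
    img = _paint_background(rng, spec)
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    boxes: List[PixelBox] = []
    occupied: List[PixelBox] = []
    max_tries = 200 * max(spec.n_flowers, 1)
    tries = 0
    margin = 0 if spec.allow_border else 15
    while len(boxes) < spec.n_flowers:
        if tries >= max_tries:
            raise PlacementError(
                f"placed {len(boxes)} of {spec.n_flowers} blobs "
                f"in {max_tries} attempts; scene too crowded")
        tries += 1
        area = _sample_area(rng, spec)
        aspect = float(rng.uniform(*spec.aspect_range))
        angle = float(rng.uniform(0, np.pi))
        cy = float(rng.uniform(margin, spec.height - margin))
        cx = float(rng.uniform(margin, spec.width - margin))
        rr, cc = _ellipse_pixels(cy, cx, area, aspect, angle,
                                 (spec.height, spec.width))
        if rr.size == 0:
            continue
        box = PixelBox(int(cc.min()), int(rr.min()),
                       int(cc.max()) + 1, int(rr.max()) + 1)
        if not spec.allow_border and (
                box.x_min < 1 or box.y_min < 1
                or box.x_max > spec.width - 1 or box.y_max > spec.height - 1):
            continue
        if spec.keep_within_tiles and _crosses_tile_border(
                box, spec.keep_within_tiles):
            continue
        # 1-px dilated separation so blobs never merge under 8-connectivity
        grown = PixelBox(max(box.x_min - 1, 0), max(box.y_min - 1, 0),
                         box.x_max + 1, box.y_max + 1)
        if any(grown.intersect(o) is not None for o in occupied):
            continue
        mask[rr, cc] = 1
        img[rr, cc] = _FLOWER + rng.normal(0, 6, size=3)
        boxes.append(box)
        occupied.append(box)
    return np.clip(img, 0, 255).astype(np.uint8), mask, boxes


# ---------------------------------------------------------------------------
# oracle detector

def _tile_rng(seed: int, tile_index: TileIndex) -> np.random.Generator:
    return np.random.default_rng((seed, tile_index[0], tile_index[1]))


def _jittered_box(box: PixelBox, dx: float, dy: float,
                  tile_size: int) -> PixelBox:
    """Translate then shift back inside the tile, preserving size."""
    x0, y0 = box.x_min + dx, box.y_min + dy
    x1, y1 = box.x_max + dx, box.y_max + dy
    sx = max(0.0, -x0) + min(0.0, tile_size - x1)
    sy = max(0.0, -y0) + min(0.0, tile_size - y1)
    return PixelBox(x0 + sx, y0 + sy, x1 + sx, y1 + sy)


def make_oracle_detector(gt_boxes: Sequence[PixelBox], grid: TileGrid,
                         noise: OracleNoise = OracleNoise()) -> Detector:
    """Detector that replays ground truth corrupted by the given noise.

    ``gt_boxes`` are global (padded-frame) boxes; they are clipped to tiles
    internally.  Per tile, each true box survives with probability
    ``1 - miss_rate``, its center jittered by a Gaussian of sigma
    ``jitter_px``, and a Poisson(``fp_per_tile``) number of spurious boxes
    is added.  Deterministic for a fixed noise seed and independent of the
    order in which tiles are visited.
    """
    per_tile: Dict[TileIndex, List[PixelBox]] = {}
    for idx in grid.indices():
        local = [b for gb in gt_boxes
                 if (b := clip_box_to_tile(gb, idx, grid)) is not None]
        if local:
            per_tile[idx] = local

    t = grid.tile_size

    def detector(tile: np.ndarray, tile_index: TileIndex
                 ) -> List[TileDetection]:
        rng = _tile_rng(noise.seed, tile_index)
        out: List[TileDetection] = []
        for box in per_tile.get(tile_index, ()):
            if rng.random() < noise.miss_rate:
                continue
            if noise.jitter_px > 0:
                dx, dy = rng.normal(0, noise.jitter_px, 2)
                box = _jittered_box(box, dx, dy, t)
            conf = float(rng.uniform(*noise.true_conf_range))
            out.append(TileDetection(box=box, confidence=conf))
        for _ in range(rng.poisson(noise.fp_per_tile)):
            w = float(rng.uniform(10, 25))
            h = float(rng.uniform(10, 25))
            x0 = float(rng.uniform(0, t - w))
            y0 = float(rng.uniform(0, t - h))
            conf = float(rng.uniform(*noise.fp_conf_range))
            out.append(TileDetection(box=PixelBox(x0, y0, x0 + w, y0 + h),
                                     confidence=conf))
        return out

    return detector


# ---------------------------------------------------------------------------
# plant-count scenarios

def simulate_plant_counts(scenario: PlantScenario,
                          n_plants: int = 7) -> pd.DataFrame:
    """Simulate two-side raw counts and reference counts for n plants.

    Returns a DataFrame with columns plant_id, side_a, side_b, raw_total,
    true_count, reference — suitable as direct input to calibration.
    Deterministic for a fixed scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    va, vb, d = scenario.visible_a, scenario.visible_b, scenario.double_count
    p_vis = va + vb
    rows = []
    lo, hi = scenario.true_count_range
    for pid in range(1, n_plants + 1):
        true_count = int(rng.integers(lo, hi + 1))
        visible = int(rng.binomial(true_count, p_vis)) if p_vis > 0 else 0
        doubled = int(rng.binomial(visible, d))
        singles = visible - doubled
        a_single = int(rng.binomial(singles, va / p_vis)) if p_vis > 0 else 0
        keep = 1.0 - scenario.miss_rate
        side_a = int(rng.binomial(a_single + doubled, keep)
                     + rng.poisson(scenario.fp_per_side))
        side_b = int(rng.binomial(singles - a_single + doubled, keep)
                     + rng.poisson(scenario.fp_per_side))
        raw_total = side_a + side_b
        if scenario.bias_slope is not None:
            reference = (scenario.bias_slope * raw_total
                         + scenario.bias_intercept
                         + rng.normal(0, scenario.reference_noise_sd))
        else:
            reference = float(true_count)
        rows.append((pid, side_a, side_b, raw_total, true_count, reference))
    return pd.DataFrame(rows, columns=["plant_id", "side_a", "side_b",
                                       "raw_total", "true_count", "reference"])
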