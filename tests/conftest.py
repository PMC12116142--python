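import numpy as np
import pytest

from tilecount.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 1200x800 scene with 20 flowers kept off 400-px tile borders."""
    spec = SceneSpec(width=1200, height=800, n_flowers=20,
                     keep_within_tiles=400, seed=11)
    image, mask, boxes = generate_scene(spec)
    return spec, image, mask, boxes


def bfs_components(mask):
    """Independent 8-connected component labeling (pure-Python flood fill)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            pix = []
            while stack:
                y, x = stack.pop()
                pix.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < h and 0 <= nx < w
                                and mask[ny, nx] and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(pix)
    return comps


def brute_force_boxes(mask):
    """Per-pixel bounding rectangles of the BFS components, as
    (x_min, y_min, x_max, y_max) half-open tuples."""
    out = []
    for pix in bfs_components(mask):
        ys = [p[0] for p in pix]
        xs = [p[1] for p in pix]
        out.append((min(xs), min(ys), max(xs) + 1, max(ys) + 1))
    return sorted(out)
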