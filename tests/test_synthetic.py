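import numpy as np
import pytest
from scipy import ndimage

from tilecount.annotation import mask_to_pixel_boxes
from tilecount.counting import CountingConfig, detect_tiles
from tilecount.geometry import PixelBox, plan_tile_grid
from tilecount.metrics import Detection, map_50_95, match_detections, \
    precision, recall
from tilecount.synthetic import (OracleNoise, PlacementError, PlantScenario,
                                 SceneSpec, generate_scene,
                                 make_oracle_detector, simulate_plant_counts)


class TestGenerateScene:
    def test_deterministic(self):
        spec = SceneSpec(width=600, height=400, n_flowers=10, seed=4)
        a = generate_scene(spec)
        b = generate_scene(spec)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_zero_flowers(self):
        img, mask, boxes = generate_scene(
            SceneSpec(width=300, height=200, n_flowers=0, seed=0))
        assert mask.sum() == 0
        assert boxes == []
        assert img.shape == (200, 300, 3)

    def test_area_band_fraction(self):
        spec = SceneSpec(width=2400, height=2000, n_flowers=500,
                         n_branches=40, seed=7)
        _, mask, boxes = generate_scene(spec)
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 500
        areas = ndimage.sum_labels(np.ones_like(mask), lab,
                                   index=range(1, n + 1))
        frac = np.mean((areas >= 280) & (areas <= 320))
        assert frac == pytest.approx(0.83, abs=0.05)

    def test_mask_components_match_boxes(self, small_scene):
        _, _, mask, boxes = small_scene
        got = sorted((b.x_min, b.y_min, b.x_max, b.y_max)
                     for b in mask_to_pixel_boxes(mask))
        want = sorted((b.x_min, b.y_min, b.x_max, b.y_max) for b in boxes)
        assert got == want

    def test_flower_sizes_plausible(self, small_scene):
        # blobs of ~300 px² are roughly 17-20 px across
        _, _, _, boxes = small_scene
        for b in boxes:
            assert 10 <= b.width <= 40
            assert 10 <= b.height <= 40

    def test_keep_within_tiles(self):
        spec = SceneSpec(width=1200, height=800, n_flowers=40,
                         keep_within_tiles=400, seed=2)
        _, _, boxes = generate_scene(spec)
        for b in boxes:
            assert b.x_min // 400 == (b.x_max - 1) // 400
            assert b.y_min // 400 == (b.y_max - 1) // 400

    def test_placement_failure_signal(self):
        with pytest.raises(PlacementError):
            generate_scene(SceneSpec(width=80, height=80, n_flowers=50,
                                     seed=0))

    def test_centroid_spread(self):
        # centroids are uniform: the mean lands near the image center
        spec = SceneSpec(width=1000, height=1000, n_flowers=300, seed=9)
        _, _, boxes = generate_scene(spec)
        cx = np.mean([(b.x_min + b.x_max) / 2 for b in boxes])
        cy = np.mean([(b.y_min + b.y_max) / 2 for b in boxes])
        assert cx == pytest.approx(500, abs=50)
        assert cy == pytest.approx(500, abs=50)


class TestOracleDetector:
    def test_zero_noise_replays_ground_truth(self, small_scene):
        spec, image, _, boxes = small_scene
        grid = plan_tile_grid(spec.width, spec.height, 400)
        detector = make_oracle_detector(boxes, grid)
        total = []
        for idx in grid.indices():
            total.extend(detector(None, idx))
        assert len(total) == len(boxes)
        assert all(d.confidence == 1.0 for d in total)

    def test_miss_rate_one(self, small_scene):
        spec, _, _, boxes = small_scene
        grid = plan_tile_grid(spec.width, spec.height, 400)
        detector = make_oracle_detector(boxes, grid,
                                        OracleNoise(miss_rate=1.0))
        assert all(not detector(None, idx) for idx in grid.indices())

    def test_miss_rate_binomial_expectation(self):
        # 2000 flowers on one big tile; detected fraction 0.80 +/- 0.02
        grid = plan_tile_grid(2000, 2000, 2000)
        boxes = [PixelBox(x, y, x + 12, y + 12)
                 for x in range(10, 1960, 44) for y in range(10, 1960, 44)]
        boxes = boxes[:2000]
        assert len(boxes) == 2000
        detector = make_oracle_detector(
            boxes, grid, OracleNoise(miss_rate=0.2, seed=8))
        dets = detector(None, (0, 0))
        assert len(dets) / 2000 == pytest.approx(0.80, abs=0.02)

    def test_false_positive_rate(self):
        grid = plan_tile_grid(4000, 4000, 400)  # 100 tiles
        detector = make_oracle_detector([], grid,
                                        OracleNoise(fp_per_tile=2.0, seed=1))
        n = sum(len(detector(None, idx)) for idx in grid.indices())
        assert n / grid.n_tiles == pytest.approx(2.0, abs=0.4)

    def test_tile_order_invariance(self, small_scene):
        spec, _, _, boxes = small_scene
        grid = plan_tile_grid(spec.width, spec.height, 400)
        noise = OracleNoise(miss_rate=0.3, fp_per_tile=0.5, jitter_px=1.0,
                            true_conf_range=(0.6, 1.0), seed=5)
        detector = make_oracle_detector(boxes, grid, noise)
        forward = {idx: detector(None, idx) for idx in grid.indices()}
        backward = {idx: detector(None, idx)
                    for idx in reversed(list(grid.indices()))}
        assert forward == backward

    def test_jitter_keeps_boxes_in_tile(self, small_scene):
        spec, _, _, boxes = small_scene
        grid = plan_tile_grid(spec.width, spec.height, 400)
        detector = make_oracle_detector(boxes, grid,
                                        OracleNoise(jitter_px=50.0, seed=2))
        for idx in grid.indices():
            for d in detector(None, idx):
                assert d.box.x_min >= 0 and d.box.y_min >= 0
                assert d.box.x_max <= 400 and d.box.y_max <= 400

    def test_noise_validation(self):
        with pytest.raises(ValueError):
            OracleNoise(miss_rate=1.5)
        with pytest.raises(ValueError):
            OracleNoise(jitter_px=-1)


class TestEndToEnd:
    def test_perfect_metrics_on_own_scene(self, small_scene):
        spec, image, _, boxes = small_scene
        grid = plan_tile_grid(spec.width, spec.height, 400)
        detector = make_oracle_detector(boxes, grid)
        dets = detect_tiles(detector, image, CountingConfig())
        m = match_detections(dets, boxes, 0.5)
        assert precision(m) == 1.0
        assert recall(m) == 1.0
        assert map_50_95(dets, {0: boxes}) == pytest.approx(1.0)


class TestSimulatePlantCounts:
    def test_defaults_raw_equals_true(self):
        df = simulate_plant_counts(PlantScenario(seed=0), 25)
        assert (df.raw_total == df.true_count).all()
        assert (df.reference == df.true_count).all()
        assert (df.raw_total == df.side_a + df.side_b).all()

    def test_byte_identical_across_runs(self):
        s = PlantScenario(visible_a=0.3, visible_b=0.3, miss_rate=0.1,
                          fp_per_side=1.0, seed=12)
        a = simulate_plant_counts(s, 7).to_csv(index=False)
        b = simulate_plant_counts(s, 7).to_csv(index=False)
        assert a == b

    def test_low_visibility_undercounts_with_slope_above_one(self):
        from tilecount.calibration import fit_ols
        s = PlantScenario(visible_a=0.3, visible_b=0.3, seed=21)
        df = simulate_plant_counts(s, 200)
        assert (df.raw_total < df.true_count).mean() > 0.95
        model = fit_ols(df.raw_total, df.reference)
        assert model.slope > 1.0
        assert model.slope == pytest.approx(1 / 0.6, rel=0.1)

    def test_double_count_overcounts(self):
        s = PlantScenario(visible_a=0.5, visible_b=0.5, double_count=0.4,
                          seed=3)
        df = simulate_plant_counts(s, 200)
        # 40% of flowers counted twice -> raw ~ 1.4x truth
        ratio = df.raw_total.sum() / df.true_count.sum()
        assert ratio == pytest.approx(1.4, abs=0.05)

    def test_known_bias_line_generates_reference(self):
        s = PlantScenario(visible_a=0.25, visible_b=0.25, bias_slope=2.0,
                          bias_intercept=5.0, reference_noise_sd=0.0, seed=6)
        df = simulate_plant_counts(s, 20)
        assert df.reference.to_numpy() == pytest.approx(
            2.0 * df.raw_total.to_numpy() + 5.0)

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            PlantScenario(visible_a=0.8, visible_b=0.8)  # sum > 1
        with pytest.raises(ValueError):
            PlantScenario(double_count=1.1)
        with pytest.raises(ValueError):
            PlantScenario(visible_a=1.5)
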