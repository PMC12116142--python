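# tilecount

Counting very small, low-contrast objects (e.g. flowers a few pixels wide)
in high-resolution whole-plant images. The pipeline: square tiling with edge
padding → per-tile detection with a pluggable detector → confidence
filtering → per-side and per-plant count aggregation → linear-regression
bias correction against reference counts. Everything is testable without a
trained neural network through a synthetic scene generator and an oracle
detector with configurable noise.

## Modules

| module | what it does |
|---|---|
| `tilecount.geometry` | tiling plans (`plan_tile_grid`), zero padding, tile extraction, tile-local ↔ global box transforms, border clipping |
| `tilecount.annotation` | binary mask → minimal bounding boxes (8-connected), normalized label-file read/write (`class x_c y_c w h`, 6 decimals), balanced tile-dataset assembly |
| `tilecount.metrics` | IoU, confidence-greedy matching, precision/recall, all-point interpolated AP, mAP@50-95 |
| `tilecount.counting` | `detect_tiles` / `count_side` / `count_plant` over a detector contract `detector(tile, tile_index) -> [TileDetection]`, confidence cutoff (default 0.5) |
| `tilecount.calibration` | OLS bias correction with t-based 95% CIs, full / leave-one-out / subset modes, MAE / MAPE / APE-std / R² error reports |
| `tilecount.synthetic` | scene generator (elliptical blobs, 83% of areas in 280–320 px²), oracle detector (miss rate, false positives, jitter), two-side plant-count scenarios |
| `tilecount.datasets` | packaged seven-plant field count table (`load_field_counts`) |

## CLI

The console script is `tilecount`:

```sh
tilecount tile image.png --out-dir tiles/ --tile-size 400
tilecount labels mask.png --out-dir labels/ --tile-size 400
tilecount evaluate --pred-dir preds/ --gt-dir labels/ --iou-threshold 0.5
tilecount count side_a.png side_b.png --backend mypkg.detectors:make_detector
tilecount calibrate counts.csv --mode full      # or loo / subset
tilecount simulate --kind counts --n-plants 7 --seed 1 --out counts.csv
tilecount simulate --kind scene --config scene.yaml --out scene_dir/
```

`calibrate` expects a CSV with `raw_total` and `reference` columns;
`count --backend` takes a dotted path to a detector (or a zero-argument
factory returning one) satisfying the detector contract.

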