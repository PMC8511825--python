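# dfcn

Dilated fully-convolutional networks (D-FCN) for multi-organ chest-CT
delineation, implemented as a self-contained, CPU-only (NumPy) toolkit:

- **HU windowing** (`dfcn.windowing`) — the window-adjustment input layer: the
  `[-300, 600]` HU range is split into three equal sub-windows, each mapped to
  one channel of the network input (`window: {lo: -300, hi: 600, channels: 3}`
  in the run config).
- **Architectures** (`dfcn.arch`) — VGG16-based FCN 32s/16s/8s construction and
  the stride-removal / dilation-compensation conversion producing D-FCN
  16s/8s/4s. The conversion is exact: with shared weights, a D-FCN score map
  subsampled at `32 / output_stride` reproduces the FCN-32s score map.
- **Engine** (`dfcn.network`) — forward *and* backward passes for dilated
  convolution, max pooling, and learnable bilinear-initialised transposed-conv
  upsampling, in pure NumPy/float32, so the networks are trainable without a
  GPU framework.
- **Metrics** (`dfcn.metrics`) — per-structure and global (micro-averaged)
  Dice, with an explicit undefined-sentinel for 0/0 and exclusion-counted
  aggregation.
- **Harness** (`dfcn.train_eval`) — deterministic dataset splitting, SGD
  training with periodic checkpoints, validation Dice curves,
  optimal-checkpoint selection (ties to the earliest iteration), and test-set
  evaluation.
- **Phantom** (`dfcn.phantom`) — a synthetic thoracic CT generator (body, two
  lungs, heart, trachea/bronchi, esophagus, spinal cord in a vertebral ring)
  so the entire pipeline runs at desk scale with no clinical data.
- **I/O + CLI** (`dfcn.io_utils`, `dfcn.cli`) — NIfTI/PNG readers and writers,
  manifest loading, checkpoint files with embedded architecture specs, and
  mask-to-contour extraction (closed polygons, outer CCW / holes CW).

## CLI

```sh
dfcn arch-info dfcn4s              # layer table, output stride, receptive field
dfcn simulate --out-dir data --n-cases 12 --image-size 96 --seed 1
dfcn train    --config cfg.yaml --out-dir run --seed 0
dfcn validate --config cfg.yaml --checkpoint-dir run --out-dir run
dfcn predict  --checkpoint run/best_checkpoint.npz --volume data/case_000_image.nii \
              --out-dir run --contours
dfcn evaluate --config cfg.yaml --checkpoint run/best_checkpoint.npz --out-dir run
```

A run config is a single YAML file with sections
`{data, window, model, training, evaluation}`; every value has a default and
CLI flags override file values. Example:

```yaml
data:
  manifest: data/manifest.csv
  split: {train: 8, val: 2, test: 2, seed: 0}
model: {variant: dfcn4s, n_classes: 7, width_multiplier: 0.25}
training:
  initial_lr: 3.0e-3
  batch_size: 1
  max_iterations: 300
  checkpoint_interval: 100
```

Class ids are `0` background and `1..6` = left lung, right lung, heart,
trachea, esophagus, spinal cord.

## Notes

- Inputs are assumed to already be in HU (no DICOM rescale handling); DICOM
  and DICOM-RT are unsupported — convert externally to NIfTI.
- `width_multiplier` scales every channel count and exists so desk-scale
  training/tests are feasible on one CPU; the published-width networks
  (multiplier 1) build and run but are slow to train without hardware
  acceleration.
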