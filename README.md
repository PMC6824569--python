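# sinoct

Fan-beam CT reconstruction from incomplete projection data via
sinogram-domain restoration with a residual U-net.

Sparse-view and limited-angle CT scans produce incomplete sinograms whose
direct filtered back-projection (FBP) reconstructions carry severe streak or
shadow artifacts. `sinoct` implements a four-stage framework that repairs the
data *before* the final reconstruction:

1. **Initial FBP** of the incomplete (zero-filled) sinogram.
2. **Re-projection** of that image to a full-size *corrupted* sinogram.
3. **Residual U-net** (27 layers at full size) that maps the normalized
   corrupted sinogram to the normalized complete one. Down-sampling is a
   trainable 2×2 stride-2 convolution; max- and mean-pooling variants are
   available for ablation.
4. **Final FBP** of the restored sinogram.

Everything is self-contained and NumPy/SciPy-based — the network layers,
backpropagation and the Nadam optimizer are implemented in this package, so
no deep-learning framework is required. A seeded random-ellipse phantom
generator with an exact (closed-form chord) fan-beam projector makes the full
train/infer loop reproducible without any external data.

## Layout

| module | contents |
| --- | --- |
| `sinoct.phantoms` | random ellipse phantoms, rasterization, analytic fan-beam projection |
| `sinoct.geometry` | `FanGeometry`, `Sinogram`, raster forward projector and its adjoint, sparse-view / limited-angle degradation, zero-fill embedding |
| `sinoct.fbp` | Ram–Lak ramp kernel and equi-spaced fan-beam weighted FBP |
| `sinoct.network` | NumPy U-net: layers with explicit backward passes, normalization, architecture table |
| `sinoct.training` | corrupted-sinogram pipeline, MSE loss, Nadam, LR decay, training loop, inference |
| `sinoct.evaluation` | PSNR / aPSNR metrics and batch reports |
| `sinoct.cli` | `sinoct generate / train / infer / evaluate` commands |

## CLI

```bash
cat > run.yaml <<EOF
seed: 0
grid_size: 128                       # geometry derives from this (180 x 185)
phantoms: {count: 12, train_count: 8, n_min: 10, n_max: 40}
degradation: {mode: sparse, factor: 6}      # or {mode: limited, max_angle_deg: 120}
network: {base_channels: 16, depth: 3, pooling_mode: strided_conv}
training: {initial_learning_rate: 2.0e-3, decay_rate: 0.1, decay_steps: 10,
           outer_iterations: 15}
paths: {dataset: data, checkpoints: ckpt, reports: reports}
EOF

sinoct generate --config run.yaml
sinoct train    --config run.yaml
sinoct infer    --config run.yaml --checkpoint ckpt/net_strided_conv.npz \
                data/sinograms/phantom_0008_incomplete.tif
sinoct evaluate --config run.yaml --checkpoint ckpt/net_strided_conv.npz \
                --out reports/metrics.csv
```

`grid_size: 512` reproduces the full-size 720-view × 731-channel
configuration (the published profile; expect hours of CPU training at that
scale). Rasters are exchanged as 32-bit float TIFF with JSON sidecars;
checkpoints are `.npz` parameter archives. Passing several `--checkpoint`
options to `evaluate` (one per pooling mode) emits a pooling-ablation report.

## Conventions

Image pixel (0,0) is top-left with x rightward and y downward; the rotation
center is the image center; view angles increase counter-clockwise with view
k of n at `k·range/n`. The source sits at distance D from the center; the
virtual flat detector passes through the center, perpendicular to the
central ray, with unit channel spacing. FBP back-projects measured views
only, weighting by the mean angular gap between consecutive measured views —
sparse-view reconstructions keep their amplitude while limited-angle
reconstructions lose the unseen sector's contribution, matching the behavior
of the standard tools these conventions follow.
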